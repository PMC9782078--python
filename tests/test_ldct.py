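import numpy as np
import pytest

from ctcfi.ldct import (DoseModel, EPS_TRANSMISSION, Sinogram, TransmissionData,
                        dequantize_hu, enhance, fbp_reconstruct, forward_project,
                        hu_to_mu, inject_noise, mu_to_hu, normalize_mu,
                        simulate_ldct, to_transmission, transmission_to_sinogram)
from ctcfi.phantom import disk_hu_volume, make_disk_slice
from ctcfi.volume import CTVolume


@pytest.fixture(scope="module")
def disk_slice():
    return make_disk_slice((128, 128), 32.0, 0.02)


@pytest.fixture(scope="module")
def angles180():
    return np.linspace(0.0, 180.0, 180, endpoint=False)


class TestDequantize:
    def test_zero_volume_lands_in_unit_interval(self):
        vol = CTVolume(np.zeros((4, 8, 8)))
        out = dequantize_hu(vol, seed=0)
        assert np.all((out.hu >= 0) & (out.hu < 1))

    def test_floor_recovers_integer_input(self):
        rng = np.random.default_rng(1)
        vol = CTVolume(rng.integers(-1000, 1000, (4, 16, 16)).astype(float))
        out = dequantize_hu(vol, seed=2)
        np.testing.assert_array_equal(np.floor(out.hu), vol.hu)

    def test_mean_shift_is_half(self):
        vol = CTVolume(np.zeros((100, 100, 100)))
        out = dequantize_hu(vol, seed=3)
        assert abs(out.hu.mean() - 0.5) < 0.002


class TestHuMuMaps:
    def test_water_and_air_anchor_points(self):
        m = DoseModel(kvp=120, mu_water=0.0161, mu_air=0.0)
        assert hu_to_mu(0.0, m) == pytest.approx(m.mu_water)
        assert hu_to_mu(-1000.0, m) == pytest.approx(m.mu_air)
        assert mu_to_hu(m.mu_water, m) == pytest.approx(0.0)
        assert mu_to_hu(m.mu_air, m) == pytest.approx(-1000.0)

    def test_direct_substitution(self):
        m = DoseModel(kvp=120, mu_water=0.2, mu_air=0.0)
        assert hu_to_mu(1000.0, m) == pytest.approx(0.4)

    @pytest.mark.parametrize("hu", [-1000.0, 0.0, 500.0])
    def test_round_trip(self, hu):
        m = DoseModel.preset(60)
        assert mu_to_hu(hu_to_mu(hu, m), m) == pytest.approx(hu, abs=1e-9)

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            DoseModel(kvp=120, mu_water=0.1, mu_air=0.1)


class TestForwardProjection:
    def test_zero_slice_projects_to_zero(self, angles180):
        sl = normalize_mu(np.zeros((64, 64)), 1.0, (0.0, 1.0))
        assert np.all(forward_project(sl, angles180).data == 0)

    def test_disk_central_ray_equals_chord(self, disk_slice):
        angles = np.linspace(0, 180, 30, endpoint=False)
        sino = forward_project(disk_slice, angles)
        central = sino.data[:, sino.data.shape[1] // 2]
        np.testing.assert_allclose(central, 2 * 32.0 * 0.02, rtol=0.02)

    def test_linearity(self, angles180):
        rng = np.random.default_rng(0)
        a = rng.random((32, 32)) * 0.01
        b = rng.random((32, 32)) * 0.01
        angles = angles180[::6]
        sa = forward_project(normalize_mu(a, 1.0, (0, 0.02)), angles).data
        sb = forward_project(normalize_mu(b, 1.0, (0, 0.02)), angles).data
        sab = forward_project(normalize_mu(a + b, 1.0, (0, 0.02)), angles).data
        np.testing.assert_allclose(sab, sa + sb, rtol=1e-6, atol=1e-9)

    def test_empty_angles_rejected(self, disk_slice):
        with pytest.raises(ValueError):
            forward_project(disk_slice, [])


class TestTransmission:
    def test_closed_forms(self):
        sino = Sinogram(np.array([[0.0], [np.log(2)]]), np.array([0.0, 90.0]))
        t = to_transmission(sino)
        np.testing.assert_allclose(t.data, [[1.0], [0.5]])

    def test_monotone_decreasing_in_line_integral(self):
        rng = np.random.default_rng(2)
        r = np.sort(rng.random(50) * 5)
        t = np.exp(-r)
        assert np.all(np.diff(t) <= 0)

    def test_exp_log_round_trip(self, disk_slice, angles180):
        sino = forward_project(disk_slice, angles180[::10])
        back = transmission_to_sinogram(to_transmission(sino))
        np.testing.assert_allclose(back.data, sino.data, atol=1e-10)

    def test_log_at_clip_floor(self):
        t = TransmissionData(np.full((2, 1), EPS_TRANSMISSION), np.array([0.0, 90.0]))
        r = transmission_to_sinogram(t)
        assert r.data[0, 0] == pytest.approx(6 * np.log(10), rel=1e-6)

    def test_below_floor_rejected(self):
        t = TransmissionData(np.array([[1e-9]]), np.array([0.0, 90.0]))
        with pytest.raises(ValueError):
            transmission_to_sinogram(t)


class TestNoiseInjection:
    def test_high_photon_count_limit(self):
        t = TransmissionData(np.full((100, 100), 0.7), np.arange(100.0) * 1.7)
        m = DoseModel(photon_count_n0=1e12, gaussian_sigma=0.0, mu_water=0.02, seed=0)
        out = inject_noise(t, m)
        np.testing.assert_allclose(out.data, 0.7, atol=1e-4)

    def test_poisson_moments(self):
        t = TransmissionData(np.full((1000, 100), 0.5), np.arange(1000) * 0.17)
        m = DoseModel(photon_count_n0=1e4, gaussian_sigma=0.0, mu_water=0.02, seed=1)
        out = inject_noise(t, m)
        assert out.data.mean() == pytest.approx(0.5, abs=0.001)
        assert out.data.var() == pytest.approx(0.5 / 1e4, rel=0.10)

    def test_gaussian_moments(self):
        t = TransmissionData(np.full((1000, 100), 0.5), np.arange(1000) * 0.17)
        m = DoseModel(photon_count_n0=1e12, gaussian_sigma=0.01, mu_water=0.02, seed=2)
        out = inject_noise(t, m)
        assert out.data.var() == pytest.approx(1e-4, rel=0.10)

    def test_nonpositive_photon_count_rejected(self):
        with pytest.raises(ValueError):
            DoseModel(photon_count_n0=0.0, mu_water=0.02)


class TestFBP:
    def test_zero_sinogram_reconstructs_zero(self, angles180):
        sino = Sinogram(np.zeros((180, 91)), angles180, output_size=64)
        rec = fbp_reconstruct(sino, "ramp", 1.0)
        assert np.abs(rec.physical).max() < 1e-12

    def test_disk_round_trip_ramp(self, disk_slice, angles180):
        sino = forward_project(disk_slice, angles180)
        rec = fbp_reconstruct(sino, "ramp", 1.0).physical
        truth = disk_slice.physical
        yy, xx = np.mgrid[:128, :128]
        interior = (yy - 63.5) ** 2 + (xx - 63.5) ** 2 < (32 - 3) ** 2
        rmse = np.sqrt(np.mean((rec - truth)[interior] ** 2))
        assert rmse <= 0.05 * 0.02

    def test_hann_smooths_more_than_ramp(self, disk_slice, angles180):
        sino = forward_project(disk_slice, angles180)
        t = to_transmission(sino)
        m = DoseModel(photon_count_n0=5e3, gaussian_sigma=0.0, mu_water=0.02, seed=5)
        noisy = transmission_to_sinogram(inject_noise(t, m))
        rec_h = fbp_reconstruct(noisy, "hann", 0.641).physical
        rec_r = fbp_reconstruct(noisy, "ramp", 1.0).physical
        yy, xx = np.mgrid[:128, :128]
        interior = (yy - 63.5) ** 2 + (xx - 63.5) ** 2 < 28 ** 2
        assert rec_h[interior].var() < rec_r[interior].var()

    def test_unknown_filter_rejected(self, disk_slice, angles180):
        sino = forward_project(disk_slice, angles180[::20])
        with pytest.raises(ValueError):
            fbp_reconstruct(sino, "butterworth", 0.5)


class TestSimulateLdct:
    def test_output_congruent_with_input(self):
        vol = disk_hu_volume(n=64, n_slices=2)
        out = simulate_ldct(vol, DoseModel.preset(60, seed=1), n_angles=60)
        assert out.hu.shape == vol.hu.shape
        assert out.spacing == vol.spacing

    def test_noise_grows_as_dose_drops(self):
        vol = disk_hu_volume(n=64)
        rms = {}
        for n0 in (1e3, 1e5):
            m = DoseModel(kvp=120, photon_count_n0=n0, gaussian_sigma=1e-3,
                          mu_water=0.0161, seed=9)
            out = simulate_ldct(vol, m, n_angles=120)
            rms[n0] = np.sqrt(np.mean((out.hu - vol.hu) ** 2))
        assert rms[1e3] > rms[1e5]

    def test_determinism(self):
        vol = disk_hu_volume(n=48)
        a = simulate_ldct(vol, DoseModel.preset(60, seed=4), n_angles=60)
        b = simulate_ldct(vol, DoseModel.preset(60, seed=4), n_angles=60)
        np.testing.assert_array_equal(a.hu, b.hu)


class TestEnhance:
    def test_none_is_identity(self):
        vol = disk_hu_volume(n=32)
        out = enhance(vol, "none")
        np.testing.assert_array_equal(out.hu, vol.hu)

    def test_gaussian_reduces_variance(self):
        rng = np.random.default_rng(0)
        vol = CTVolume(rng.normal(0, 50, (8, 32, 32)))
        out = enhance(vol, "gaussian")
        assert out.hu.var() < vol.hu.var()

    def test_tv_improves_noisy_disk(self):
        vol = disk_hu_volume(n=64)
        noisy = simulate_ldct(vol, DoseModel.preset(60, seed=3), n_angles=120)
        den = enhance(noisy, "tv")
        rmse_noisy = np.sqrt(np.mean((noisy.hu - vol.hu) ** 2))
        rmse_den = np.sqrt(np.mean((den.hu - vol.hu) ** 2))
        assert rmse_den < rmse_noisy

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            enhance(disk_hu_volume(n=16), "wavelet")
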