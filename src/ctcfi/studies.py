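"""Benchmark studies exercising the pipeline end to end on phantoms.

These are the package's reference experiments: dose-simulation round
trips, noise-moment checks, graph-cut optimality sampling, the
segmentation-vs-dose sweep, filet geometry checks and the synthetic
polyp-detection study.  Problem sizes are chosen to run on a single CPU
in minutes; every function takes an explicit seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import ldct
from .detect import detect_blobs, match_detections
from .filet import build_rig, fuse_curvature, project_annotations, render_filet, sweep_rings
from .phantom import (PolypSpec, disk_hu_volume, make_colon_phantom,
                      make_tube_mesh, straight_tube_spec, tube_bump_annotations)
from .segmentation import (IntensityModel, LabelVolume, MRFConfig,
                           SegmentationFailure, graphcut_segment, iou,
                           mrf_energy, segment_colon)
from .surface import Centerline, compute_vertex_curvature
from .volume import CTVolume


def dose_roundtrip_rms(seed: int = 0, n: int = 128, n_angles: int = 360) -> float:
    """RMS HU error of the full simulation chain in the high-dose limit.

    A 128^2 soft-tissue disk in air is pushed through dequantisation,
    projection, transmission, (noise-free) detection and ramp FBP; the
    residual is discretization error only.
    """
    vol = disk_hu_volume(n=n, n_slices=1)
    model = ldct.DoseModel.preset(120, seed=seed)
    model.photon_count_n0 = 1e12
    model.gaussian_sigma = 0.0
    out = ldct.simulate_ldct(vol, model, n_angles=n_angles,
                             filter_name="ramp", frequency_scaling=1.0)
    return float(np.sqrt(np.mean((out.hu - vol.hu) ** 2)))


def transmission_noise_moments(seed: int = 0, n_draws: int = 100_000,
                               t_value: float = 0.5, n0: float = 1e4):
    """Sample mean and variance of the injected transmission noise."""
    shape = (n_draws // 100, 100)
    t = ldct.TransmissionData(np.full(shape, t_value),
                              np.arange(shape[0]) * 179.0 / shape[0])
    model = ldct.DoseModel(photon_count_n0=n0, gaussian_sigma=0.0,
                           mu_water=0.02, seed=seed)
    out = ldct.inject_noise(t, model)
    return float(out.data.mean()), float(out.data.var())


def graphcut_optimality(seed: int = 0, n_instances: int = 20) -> float:
    """Fraction of random 2x2x2 MRF instances where the cut labeling's
    energy equals the exhaustive-enumeration minimum exactly."""
    rng = np.random.default_rng(seed)
    model = IntensityModel(-1000, 100, 40, 100)
    config = MRFConfig(lambda_pairwise=1.5)
    exact = 0
    for _ in range(n_instances):
        hu = rng.normal(-500, 400, (2, 2, 2))
        vol = CTVolume(hu)
        best = np.inf
        for bits in itertools.product([0, 1], repeat=8):
            lab = LabelVolume(np.array(bits, dtype=np.uint8).reshape(2, 2, 2))
            best = min(best, mrf_energy(vol, lab, model, config))
        out = graphcut_segment(vol, model, config)
        exact += mrf_energy(vol, out, model, config) == best
    return exact / n_instances


def segmentation_dose_study(seed: int = 0, n_seeds: int = 10,
                            grid_shape=(32, 64, 64), lumen_radius_mm: float = 10.0,
                            kvps=(120, 80, 60, 30), n_angles: int = 180) -> dict:
    """Colon IoU vs. phantom truth across simulated tube voltages.

    Straight-tube phantoms (analytic truth) are simulated at each preset
    voltage and re-segmented; returns per-voltage IoU lists.  A failed
    segmentation scores 0.
    """
    results: dict[int, list[float]] = {kvp: [] for kvp in kvps}
    for i in range(n_seeds):
        spec = straight_tube_spec(grid_shape, lumen_radius_mm=lumen_radius_mm,
                                  seed=seed * 1000 + i)
        volume, truth = make_colon_phantom(spec)
        for kvp in kvps:
            model = ldct.DoseModel.preset(kvp, seed=seed * 1000 + i * 10 + kvp)
            sim = ldct.simulate_ldct(volume, model, n_angles=n_angles)
            try:
                seg = segment_colon(sim)
                results[kvp].append(iou(truth.colon_mask, seg.air_mask))
            except SegmentationFailure:
                results[kvp].append(0.0)
    return results


def curvature_fixture_errors() -> dict:
    """Curvature accuracy on the analytic sphere / cylinder / plane fixtures."""
    import trimesh

    from .surface import SurfaceMesh

    ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    sphere = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    sphere.normals = np.asarray(ico.vertices) / 10.0
    sphere = compute_vertex_curvature(sphere)
    sphere_err = abs(float(sphere.curvature.mean()) * 10.0 - 1.0)

    tube = compute_vertex_curvature(make_tube_mesh(80.0, 10.0, []))
    inner = (tube.vertices[:, 0] > 10) & (tube.vertices[:, 0] < 70)
    cyl_err = abs(abs(float(tube.curvature[inner].mean())) * 20.0 - 1.0)

    n = 20
    gx, gy = np.meshgrid(np.arange(float(n)), np.arange(float(n)))
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    plane = SurfaceMesh(verts, np.array(faces))
    plane.normals = np.tile([0.0, 0.0, 1.0], (n * n, 1))
    plane = compute_vertex_curvature(plane)
    interior = ((verts[:, 0] > 2) & (verts[:, 0] < 17)
                & (verts[:, 1] > 2) & (verts[:, 1] < 17))
    plane_err = float(np.abs(plane.curvature[interior]).max())
    return {"sphere_rel_err": sphere_err, "cylinder_rel_err": cyl_err,
            "plane_abs_err": plane_err}


def filet_geometry_study() -> dict:
    """Ring-face coverage and bump localisation on the tube fixture."""
    length, radius = 80.0, 10.0
    bump = PolypSpec(0.5, 90.0, 3.0)
    mesh = compute_vertex_curvature(
        make_tube_mesh(length, radius, [bump], n_theta=96, axial_step_mm=1.0))
    axis = np.column_stack([np.linspace(0, length, 41), np.zeros(41), np.zeros(41)])
    cl = Centerline(points=axis)
    rig = build_rig(cl, 40.0)
    filet = fuse_curvature(render_filet(mesh, rig, 20.0), mesh)

    cents = mesh.face_centroids
    ring = np.flatnonzero((cents[:, 0] >= filet.ring_range[0])
                          & (cents[:, 0] <= filet.ring_range[1]))
    coverage = float(np.isin(ring, np.unique(filet.cell_map)).mean())

    dets = detect_blobs(filet)
    col_expect = float(np.argmin(np.abs(filet.azimuth_deg - 90.0)))
    row_expect = float(np.argmin(np.abs(filet.arc_mm - 40.0)))
    if dets:
        x, y, w, h = max(dets, key=lambda d: d.score).box
        offset = max(abs(x + w / 2 - col_expect), abs(y + h / 2 - row_expect))
    else:
        offset = float("inf")
    return {"ring_face_coverage": coverage, "bump_center_offset_px": float(offset)}


def _random_tube_polyps(rng: np.random.Generator, length: float, radius: float,
                        n_polyps: int) -> list[PolypSpec]:
    """Non-overlapping wall bumps, radius >= 3 mm (6 mm size class)."""
    placed: list[PolypSpec] = []
    guard = 0
    while len(placed) < n_polyps and guard < 200:
        guard += 1
        cand = PolypSpec(arc_position=float(rng.uniform(0.2, 0.8)),
                         azimuth_deg=float(rng.uniform(0, 360)),
                         radius_mm=float(rng.uniform(3.0, 5.0)))
        ok = True
        for p in placed:
            dz = (cand.arc_position - p.arc_position) * length
            dphi = np.deg2rad(abs(((cand.azimuth_deg - p.azimuth_deg) + 180) % 360 - 180))
            sep = np.hypot(dz, radius * dphi)
            if sep < cand.radius_mm + p.radius_mm + 4.0:
                ok = False
                break
        if ok:
            placed.append(cand)
    return placed


def detection_study(seed: int = 0, n_phantoms: int = 20,
                    length: float = 60.0, radius: float = 10.0,
                    match_iou: float = 0.3) -> dict:
    """Per-polyp recall and false positives per ring of the blob baseline
    over seeded tube phantoms carrying 1-3 polyps of the 6 mm+ size class."""
    rng = np.random.default_rng(seed)
    n_truth = n_found = n_fp = n_rings = 0
    axis = np.column_stack([np.linspace(0, length, 31), np.zeros(31), np.zeros(31)])
    cl = Centerline(points=axis)
    for _ in range(n_phantoms):
        polyps = _random_tube_polyps(rng, length, radius, int(rng.integers(1, 4)))
        mesh = compute_vertex_curvature(
            make_tube_mesh(length, radius, polyps, n_theta=96, axial_step_mm=1.0))
        annotations = tube_bump_annotations(length, radius, polyps)
        frames = sweep_rings(mesh, cl, truth=annotations)
        n_rings += len(frames)
        found: set[int] = set()
        for frame in frames:
            dets = detect_blobs(frame)
            tboxes = [b for _, b in frame.boxes]
            assignment, _ = match_detections(dets, tboxes, match_iou,
                                             wrap_width=frame.shape[1])
            for d, a in zip(dets, assignment):
                if a is None:
                    n_fp += 1
                else:
                    found.add(frame.boxes[a][0])
        n_truth += len(annotations)
        n_found += len(found)
    return {"per_polyp_recall": n_found / n_truth if n_truth else float("nan"),
            "false_positives_per_ring": n_fp / n_rings if n_rings else float("nan"),
            "n_polyps": n_truth, "n_rings": n_rings}


def reproducibility_study(seed: int = 0, out_root=None) -> bool:
    """Two identical pipeline runs must produce digest-identical outputs."""
    import tempfile
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline

    config = PipelineConfig(
        seed=seed,
        phantom={"grid_shape": (48, 48, 48), "lumen_radius_mm": 8.0,
                 "polyps": [{"arc_position": 0.5, "azimuth_deg": 90.0,
                             "radius_mm": 3.0}]})
    with tempfile.TemporaryDirectory(dir=out_root) as tmp:
        m1 = run_pipeline(config, Path(tmp) / "a")
        m2 = run_pipeline(config, Path(tmp) / "b")
        return bool(m1.files and m1.files == m2.files)
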