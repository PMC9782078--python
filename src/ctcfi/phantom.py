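"""Synthetic abdominal CT phantoms with known colon geometry.

The generator renders a soft-tissue body (elliptical cross-section) in an
exterior-air field, a bone-like rod, a tubular colon lumen of air following
a smooth spline path, optional tagged-fluid pools occupying the
gravitationally lowest part of the lumen, and wall-attached polyps
(hemispherical sessile or sphere-on-stalk pedunculated).  Every structure
is also reported as voxel-exact ground truth, so segmentation, surface,
rendering and detection stages are all testable without any data download.

Hounsfield classes default to air −1000±15, soft tissue 40±20, fluid
500±30, bone 900±50 — distinct, realistic bands.  Voxels on class
boundaries get partial-volume HU from 2×2×2 sub-voxel occupancy sampling,
so walls are not unrealistically sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import parallel_transport_frames, resample_path
from .ldct import AttenuationSlice, normalize_mu
from .surface import SurfaceMesh
from .volume import CTVolume

DEFAULT_TISSUE_MODEL = {
    "air": (-1000.0, 15.0),
    "soft_tissue": (40.0, 20.0),
    "fluid": (500.0, 30.0),
    "bone": (900.0, 50.0),
}

_GRAVITY_AXES = {"+z": (0, +1), "-z": (0, -1), "+y": (1, +1),
                 "-y": (1, -1), "+x": (2, +1), "-x": (2, -1)}


@dataclass
class PolypSpec:
    """One wall-attached polyp.

    ``arc_position`` is the normalized position along the colon path in
    [0, 1]; ``azimuth_deg`` the angular position on the wall in the
    transported path frame; ``radius_mm`` the head radius.
    """

    arc_position: float
    azimuth_deg: float
    radius_mm: float
    morphology: str = "sessile"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("polyp radius must be positive")
        if not 0.0 <= self.arc_position <= 1.0:
            raise ValueError("arc_position must be in [0, 1]")
        if not 0.0 <= self.azimuth_deg < 360.0:
            raise ValueError("azimuth_deg must be in [0, 360)")
        if self.morphology not in ("sessile", "pedunculated"):
            raise ValueError(f"unknown morphology {self.morphology!r}")


@dataclass
class PolypAnnotation:
    center_voxel: tuple[int, int, int]
    center_mm: tuple[float, float, float]
    radius_mm: float
    morphology: str

    def to_json_dict(self) -> dict:
        return {"center_voxel": list(self.center_voxel),
                "center_mm": list(self.center_mm),
                "radius_mm": self.radius_mm, "morphology": self.morphology}


@dataclass
class GroundTruth:
    """Voxel-exact truth for one phantom: lumen air, fluid, polyps."""

    colon_mask: np.ndarray
    fluid_mask: np.ndarray
    polyp_annotations: list[PolypAnnotation] = field(default_factory=list)
    path_mm: np.ndarray | None = None   # the generating centerline samples

    def __post_init__(self) -> None:
        if (self.colon_mask & self.fluid_mask).any():
            raise ValueError("colon and fluid masks must be disjoint")


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)      # (nz, ny, nx)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    path_control_points: np.ndarray | None = None        # (n, 3) mm, (z,y,x)
    lumen_radius_mm: float = 9.0
    tissue_model: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MODEL))
    polyps: list[PolypSpec] = field(default_factory=list)
    fluid_fill_fraction: float = 0.0
    fluid_segments: list[tuple[float, float]] = field(default_factory=list)
    gravity_axis: str = "+y"
    body: bool = True
    bone: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen_radius_mm must be positive")
        if self.gravity_axis not in _GRAVITY_AXES:
            raise ValueError(f"gravity_axis must be one of {sorted(_GRAVITY_AXES)}")
        means = {k: v[0] for k, v in self.tissue_model.items()}
        if not (means["air"] < means["soft_tissue"] < means["fluid"] <= means["bone"]):
            raise ValueError("class HU means must be ordered air < soft tissue < fluid <= bone")
        if not 0.0 <= self.fluid_fill_fraction <= 1.0:
            raise ValueError("fluid_fill_fraction must be in [0, 1]")
        if self.path_control_points is None:
            self.path_control_points = _default_path(self.grid_shape, self.spacing)
        self.path_control_points = np.asarray(self.path_control_points, dtype=np.float64)
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        if (self.path_control_points < 0).any() or (self.path_control_points >= extent).any():
            raise ValueError("path control points must lie inside the grid")


def _default_path(grid_shape, spacing) -> np.ndarray:
    """Gentle S-curve through the middle of the grid along z."""
    nz, ny, nx = grid_shape
    ez, ey, ex = nz * spacing[0], ny * spacing[1], nx * spacing[2]
    z = np.linspace(0.08 * ez, 0.92 * ez, 7)
    y = ey * (0.5 + 0.08 * np.sin(np.linspace(0, 2 * np.pi, 7)))
    x = ex * (0.5 + 0.08 * np.cos(np.linspace(0, 1.5 * np.pi, 7)))
    return np.column_stack([z, y, x])


def straight_tube_spec(grid_shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0),
                       lumen_radius_mm=9.0, **kwargs) -> PhantomSpec:
    """A straight axial tube through the grid center — the analytic fixture."""
    nz, ny, nx = grid_shape
    extent = np.asarray(grid_shape) * np.asarray(spacing)
    pts = np.array([[0.02 * extent[0], extent[1] / 2, extent[2] / 2],
                    [0.98 * extent[0] - 1e-6, extent[1] / 2, extent[2] / 2]])
    return PhantomSpec(grid_shape=grid_shape, spacing=spacing,
                       path_control_points=pts, lumen_radius_mm=lumen_radius_mm, **kwargs)


def _polyp_solid_distance(pts: np.ndarray, wall: np.ndarray, inward: np.ndarray,
                          spec: PolypSpec) -> np.ndarray:
    """Signed distance (mm) from points to the polyp solid (negative inside)."""
    r = spec.radius_mm
    if spec.morphology == "sessile":
        return np.linalg.norm(pts - wall, axis=-1) - r
    # pedunculated: stalk (radius 0.4 r, length r) + head sphere at its end
    head = wall + inward * r
    d_head = np.linalg.norm(pts - head, axis=-1) - r
    rel = pts - wall
    t = np.clip(rel @ inward, 0.0, r)
    closest = wall + t[..., None] * inward
    d_stalk = np.linalg.norm(pts - closest, axis=-1) - 0.4 * r
    return np.minimum(d_head, d_stalk)


def make_colon_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Render the phantom volume and its voxel-exact ground truth."""
    nz, ny, nx = spec.grid_shape
    sp = np.asarray(spec.spacing)
    rng = np.random.default_rng(spec.seed)
    r = spec.lumen_radius_mm

    path = resample_path(spec.path_control_points, 0.4 * float(sp.min()))
    tangents, normals, binormals = parallel_transport_frames(path)
    tree = cKDTree(path)

    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    centers = np.column_stack([zz.ravel() * sp[0], yy.ravel() * sp[1], xx.ravel() * sp[2]])
    dist, nearest = tree.query(centers, workers=-1)
    # flat tube ends: drop the spherical caps past the path end points
    # (any voxel near an end point but axially beyond it is cap material)
    reach = 1.5 * r
    d_lo = centers - path[0]
    d_hi = centers - path[-1]
    end_lo = (np.linalg.norm(d_lo, axis=1) <= reach) & (d_lo @ tangents[0] < 0)
    end_hi = (np.linalg.norm(d_hi, axis=1) <= reach) & (d_hi @ tangents[-1] > 0)
    dist[end_lo | end_hi] = np.inf
    dist = dist.reshape(spec.grid_shape)
    nearest = nearest.reshape(spec.grid_shape)

    # sub-voxel occupancy on the wall band only (2x2x2 subsamples)
    half_diag = 0.5 * float(np.linalg.norm(sp))
    occ = (dist < r).astype(np.float64)
    band = np.abs(dist - r) <= half_diag
    if band.any():
        bc = centers.reshape(nz, ny, nx, 3)[band]
        acc = np.zeros(len(bc))
        for oz in (-0.25, 0.25):
            for oy in (-0.25, 0.25):
                for ox in (-0.25, 0.25):
                    off = np.array([oz, oy, ox]) * sp
                    d_sub, _ = tree.query(bc + off, workers=-1)
                    acc += d_sub < r
        occ[band] = acc / 8.0

    # polyps carve tissue back out of the lumen
    annotations: list[PolypAnnotation] = []
    wall_points = []
    for p in spec.polyps:
        i = int(round(p.arc_position * (len(path) - 1)))
        phi = np.deg2rad(p.azimuth_deg)
        radial = np.cos(phi) * normals[i] + np.sin(phi) * binormals[i]
        wall = path[i] + r * radial
        inward = -radial
        wall_points.append((wall, p))
        if p.morphology == "sessile":
            center = wall
        else:
            center = wall + inward * p.radius_mm
        cv = np.round(center / sp).astype(int)
        if (cv < 0).any() or (cv >= np.array(spec.grid_shape)).any():
            raise ValueError("polyp lies outside the grid")
        annotations.append(PolypAnnotation(tuple(int(v) for v in cv),
                                           tuple(float(v) for v in center),
                                           p.radius_mm, p.morphology))
    for a in range(len(wall_points)):
        for b in range(a + 1, len(wall_points)):
            wa, pa = wall_points[a]
            wb, pb = wall_points[b]
            if np.linalg.norm(wa - wb) < pa.radius_mm + pb.radius_mm:
                raise ValueError(f"polyps {a} and {b} overlap")

    for wall, p in wall_points:
        i = int(round(p.arc_position * (len(path) - 1)))
        phi = np.deg2rad(p.azimuth_deg)
        inward = -(np.cos(phi) * normals[i] + np.sin(phi) * binormals[i])
        pad = 2 * p.radius_mm + float(sp.max())
        lo = np.maximum(np.floor((wall - pad) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((wall + pad) / sp).astype(int) + 1, np.array(spec.grid_shape))
        sl = tuple(slice(lo[k], hi[k]) for k in range(3))
        bz, by, bx = np.meshgrid(np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]),
                                 np.arange(lo[2], hi[2]), indexing="ij")
        pts = np.stack([bz * sp[0], by * sp[1], bx * sp[2]], axis=-1)
        p_occ = np.zeros(pts.shape[:3])
        for oz in (-0.25, 0.25):
            for oy in (-0.25, 0.25):
                for ox in (-0.25, 0.25):
                    off = np.array([oz, oy, ox]) * sp
                    p_occ += _polyp_solid_distance(pts + off, wall, inward, p) < 0
        p_occ /= 8.0
        occ[sl] = occ[sl] * (1.0 - p_occ)

    # majority-air convention: exact-half occupancy voxels are wall, not lumen
    lumen = occ > 0.5

    # tagged fluid: lowest cross-section fraction of designated segments
    fluid = np.zeros(spec.grid_shape, dtype=bool)
    if spec.fluid_fill_fraction > 0 and spec.fluid_segments:
        axis, sign = _GRAVITY_AXES[spec.gravity_axis]
        g_hat = np.zeros(3)
        g_hat[axis] = sign
        t_norm = nearest / (len(path) - 1)
        g_coord = (centers.reshape(nz, ny, nx, 3) - path[nearest]) @ g_hat
        in_segment = np.zeros(spec.grid_shape, dtype=bool)
        for t0, t1 in spec.fluid_segments:
            in_segment |= (t_norm >= t0) & (t_norm <= t1)
        depth = r * (1.0 - 2.0 * spec.fluid_fill_fraction)
        fluid = lumen & in_segment & (g_coord >= depth)
    lumen = lumen & ~fluid

    # compose HU
    model = spec.tissue_model
    hu_mean = np.full(spec.grid_shape, model["soft_tissue"][0])
    hu_sigma = np.full(spec.grid_shape, model["soft_tissue"][1])
    if spec.body:
        cy, cx = (ny - 1) / 2, (nx - 1) / 2
        ay, ax_ = 0.45 * ny, 0.45 * nx
        outside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax_) ** 2 > 1.0
        hu_mean[outside] = model["air"][0]
        hu_sigma[outside] = model["air"][1]
    else:
        outside = np.zeros(spec.grid_shape, dtype=bool)
    if spec.bone and spec.body:
        # spine-like rod, posterior and well clear of the colon course so
        # gravity fluid-growing from the lumen cannot reach it
        by0, bx0 = (ny - 1) / 2 + 0.36 * ny, (nx - 1) / 2
        rod = ((yy - by0) * sp[1]) ** 2 + ((xx - bx0) * sp[2]) ** 2 <= 2.5 ** 2
        rod &= ~outside
        hu_mean[rod] = model["bone"][0]
        hu_sigma[rod] = model["bone"][1]
    # lumen air by partial-volume blending
    hu_mean = occ * model["air"][0] + (1 - occ) * hu_mean
    hu_sigma = occ * model["air"][1] + (1 - occ) * hu_sigma
    hu_mean[fluid] = model["fluid"][0]
    hu_sigma[fluid] = model["fluid"][1]

    hu = hu_mean + rng.standard_normal(spec.grid_shape) * hu_sigma
    truth = GroundTruth(colon_mask=lumen & ~outside, fluid_mask=fluid,
                        polyp_annotations=annotations, path_mm=path)
    return CTVolume(hu, tuple(sp)), truth


def make_tube_mesh(length_mm: float, radius_mm: float,
                   bumps: list[PolypSpec] | None = None,
                   n_theta: int = 96, axial_step_mm: float = 1.0) -> SurfaceMesh:
    """Open-ended cylinder mesh with inward normals and hemispherical bumps.

    The tube axis runs along z through (y, x) = (0, 0); azimuth is measured
    in the parallel-transported frame of the straight axis, matching the
    filet renderer's convention.  Bumps (any morphology) are rendered as
    hemispheres of the given radius protruding into the lumen.
    """
    if length_mm <= 0 or radius_mm <= 0:
        raise ValueError("length_mm and radius_mm must be positive")
    bumps = bumps or []
    n_rows = max(int(round(length_mm / axial_step_mm)) + 1, 2)
    zs = np.linspace(0.0, length_mm, n_rows)
    axis_pts = np.column_stack([zs, np.zeros(n_rows), np.zeros(n_rows)])
    _, N, B = parallel_transport_frames(axis_pts)
    phis = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)

    rho = np.full((n_rows, n_theta), radius_mm)
    for b in bumps:
        zb = b.arc_position * length_mm
        phib = np.deg2rad(b.azimuth_deg)
        dphi = np.angle(np.exp(1j * (phis[None, :] - phib)))
        s2 = (radius_mm * dphi) ** 2 + (zs[:, None] - zb) ** 2
        rho = np.minimum(rho, radius_mm - np.sqrt(np.clip(b.radius_mm ** 2 - s2, 0.0, None)))

    cosb = np.cos(phis)[None, :, None]
    sinb = np.sin(phis)[None, :, None]
    verts = (axis_pts[:, None, :] +
             rho[:, :, None] * (cosb * N[:, None, :] + sinb * B[:, None, :]))
    verts = verts.reshape(-1, 3)

    faces = []
    for i in range(n_rows - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b_ = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b_, c])
            faces.append([b_, d, c])
    mesh = SurfaceMesh(verts, np.asarray(faces))
    tm = mesh.as_trimesh()
    vn = np.asarray(tm.vertex_normals, dtype=np.float64).copy()
    # orient normals toward the axis (into the lumen)
    to_axis = -verts.copy()
    to_axis[:, 0] = 0.0
    if np.mean(np.einsum("ij,ij->i", vn, to_axis)) < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
        vn = -vn
    mesh.normals = vn / np.linalg.norm(vn, axis=1, keepdims=True)
    return mesh


def tube_bump_annotations(length_mm: float, radius_mm: float,
                          bumps: list[PolypSpec]) -> list[PolypAnnotation]:
    """Ground-truth annotations for :func:`make_tube_mesh` bumps (mm space)."""
    out = []
    n_rows = 2
    axis_pts = np.array([[0.0, 0, 0], [length_mm, 0, 0]])
    _, N, B = parallel_transport_frames(axis_pts)
    for b in bumps:
        phib = np.deg2rad(b.azimuth_deg)
        center = (np.array([b.arc_position * length_mm, 0, 0]) +
                  radius_mm * (np.cos(phib) * N[0] + np.sin(phib) * B[0]))
        out.append(PolypAnnotation(tuple(int(round(v)) for v in center),
                                   tuple(float(v) for v in center),
                                   b.radius_mm, b.morphology))
    return out


def make_disk_slice(shape: tuple[int, int], disk_radius_mm: float,
                    attenuation: float, spacing_mm: float = 1.0) -> AttenuationSlice:
    """Centered uniform disk with an antialiased (sub-pixel occupancy) edge."""
    ny, nx = shape
    rad_px = disk_radius_mm / spacing_mm
    if rad_px > min(ny, nx) / 2:
        raise ValueError("disk does not fit inside the slice")
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    yy, xx = np.mgrid[:ny, :nx]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    occ = np.clip(rad_px + 0.5 - d, 0.0, 1.0)
    mu = occ * attenuation
    hi = max(attenuation, 1e-12)
    return AttenuationSlice(mu / hi, 0.0, hi, spacing_mm)


def disk_hu_volume(n: int = 128, radius_frac: float = 0.25, n_slices: int = 1,
                   tissue_hu: float = 40.0, background_hu: float = -1000.0,
                   spacing_mm: float = 1.0) -> CTVolume:
    """HU disk-in-air volume used for dose round-trip studies."""
    cy = cx = (n - 1) / 2
    yy, xx = np.mgrid[:n, :n]
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    occ = np.clip(radius_frac * n + 0.5 - d, 0.0, 1.0)
    sl = occ * tissue_hu + (1 - occ) * background_hu
    return CTVolume(np.repeat(sl[None], n_slices, axis=0),
                    (spacing_mm, spacing_mm, spacing_mm))
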