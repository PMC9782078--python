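"""Fly-In filet rendering: unwrap a colon ring into a 360° image.

A ring rig of k virtual cameras sits on a centerline point, principal axes
pointing radially outward in the parallel-transported frame, each owning a
360/k-degree azimuth sector (plus a small overlap margin).  The ring's
interior surface is rendered into a "filet": a 2-D image whose columns are
azimuth in [0, 360) and whose rows are arc length along the centerline.
Pixels are produced by casting radial rays from the centerline (one
cylindrical unwrap, so a surface point's column is exactly its geometric
azimuth and no stitching distortion can appear at sector seams); the rig
supplies sector ownership and per-cell visibility scoring.

Visibility of a surface cell follows three factors: the angle alpha
between the projection direction and the owning camera's principal axis,
the angle phi between the projection direction and the cell normal, and
the focal-length/distance ratio.  The loss is the documented convention

    FL_v = 1 - cos(alpha) * max(0, cos(phi)) * min(1, f / d)

which is 0 for an ideal frontal view within focus range and grows
monotonically in each factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import GroundTruth, PolypAnnotation
from .surface import Centerline, SurfaceMesh, curvature_to_rgb


@dataclass
class CameraRig:
    """Ring of k cameras at one centerline point."""

    centerline: Centerline
    arc_position_mm: float
    k: int = 8
    focal_length_mm: float = 10.0
    near_mm: float = 0.5
    far_mm: float = 60.0
    sector_margin_deg: float = 5.0
    center: np.ndarray = field(init=False)
    tangent: np.ndarray = field(init=False)
    frame_normal: np.ndarray = field(init=False)
    frame_binormal: np.ndarray = field(init=False)
    looks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 cameras")
        if not 0.0 <= self.arc_position_mm <= self.centerline.length:
            raise ValueError(
                f"arc position {self.arc_position_mm} outside centerline "
                f"range [0, {self.centerline.length:.1f}]")
        p, t, n, b = self.centerline.frame_at(self.arc_position_mm)
        self.center, self.tangent = p, t
        self.frame_normal, self.frame_binormal = n, b
        az = np.deg2rad(self.camera_azimuths_deg)
        self.looks = np.cos(az)[:, None] * n + np.sin(az)[:, None] * b

    @property
    def camera_azimuths_deg(self) -> np.ndarray:
        return np.arange(self.k) * (360.0 / self.k)

    @property
    def fov_deg(self) -> float:
        """Per-camera azimuthal field of view (sector plus overlap margin)."""
        return 360.0 / self.k + 2 * self.sector_margin_deg

    def camera_of_azimuth(self, azimuth_deg) -> np.ndarray:
        """Sector owner: seams cut at sector midlines between cameras."""
        step = 360.0 / self.k
        return (np.round(np.asarray(azimuth_deg) / step).astype(int)) % self.k


def build_rig(centerline: Centerline, arc_position_mm: float, k: int = 8,
              focal_length_mm: float = 10.0, **kwargs) -> CameraRig:
    """Place a ring rig of k cameras at the given arc position."""
    return CameraRig(centerline, arc_position_mm, k=k,
                     focal_length_mm=focal_length_mm, **kwargs)


def visualization_loss(alpha, phi, f: float, d):
    """FL_v = 1 - cos(alpha)·max(0, cos(phi))·min(1, f/d), in [0, 1].

    Angles in radians; ``f`` and ``d`` in mm, d > 0.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("cell distance d must be positive")
    gain = np.cos(alpha) * np.maximum(0.0, np.cos(phi)) * np.minimum(1.0, f / d)
    return np.clip(1.0 - gain, 0.0, 1.0)


@dataclass
class VisCellScore:
    """Per-pixel visibility factors for the rendered cells."""

    alpha: np.ndarray      # rad, angle(ray, camera look)
    phi: np.ndarray        # rad, angle(projection direction, cell normal)
    distance: np.ndarray   # mm
    loss: np.ndarray       # FL_v in [0, 1]
    flagged: np.ndarray    # loss above the visibility cutoff


@dataclass
class FiletImage:
    """Unwrapped colon-ring image with its pixel->surface-cell map."""

    rgb: np.ndarray                    # (rows, cols, 3) float in [0,1]
    cell_map: np.ndarray               # (rows, cols) face index, -1 = no hit
    ring_range: tuple[float, float]    # arc interval [s0, s1] mm
    azimuth_deg: np.ndarray            # (cols,) pixel center azimuths
    arc_mm: np.ndarray                 # (rows,) pixel center arc positions
    vis: VisCellScore | None = None
    curvature: np.ndarray | None = None      # (rows, cols) mm^-1, after fusion
    curvature_range: float | None = None
    boxes: list[tuple[int, tuple[int, int, int, int]]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_map.shape


def _ray_cast_rows(origins, dirs, tri, t_min):
    """Chunked Möller–Trumbore; returns (face index or -1, distance) per ray."""
    v0, e1, e2 = tri
    n_rays = len(origins)
    best_t = np.full(n_rays, np.inf)
    best_f = np.full(n_rays, -1, dtype=np.int64)
    if len(v0) == 0:
        return best_f, best_t
    chunk = max(1, int(4e6 // max(len(v0), 1)))
    eps = 1e-9
    for i0 in range(0, n_rays, chunk):
        o = origins[i0:i0 + chunk][:, None, :]
        dvec = dirs[i0:i0 + chunk][:, None, :]
        h = np.cross(dvec, e2[None])
        a = np.einsum("rfc,fc->rf", h, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            finv = 1.0 / a
            s = o - v0[None]
            u = finv * np.einsum("rfc,rfc->rf", s, h)
            q = np.cross(s, e1[None])
            v = finv * np.einsum("rfc,rfc->rf", q, dvec)
            t = finv * np.einsum("rfc,fc->rf", q, e2)
        with np.errstate(invalid="ignore"):
            valid = ((np.abs(a) > eps) & (u >= -1e-7) & (v >= -1e-7)
                     & (u + v <= 1 + 1e-7) & (t > t_min))
        t = np.where(valid, t, np.inf)
        jbest = np.argmin(t, axis=1)
        rows = np.arange(len(jbest))
        tb = t[rows, jbest]
        hit = np.isfinite(tb)
        best_t[i0:i0 + chunk][hit] = tb[hit]
        best_f[i0:i0 + chunk][hit] = jbest[hit]
    return best_f, best_t


def render_filet(mesh: SurfaceMesh, rig: CameraRig, ring_length_mm: float = 20.0,
                 resolution: tuple[int, int] | None = None,
                 visibility_cutoff: float = 0.95) -> FiletImage:
    """Render the colon ring around the rig into an unwrapped filet image.

    ``resolution`` is (rows, cols); defaults to 2 px/mm of arc by 1 px/deg.
    Raises if the rig center is not inside the lumen.
    """
    cl = rig.centerline
    s0 = rig.arc_position_mm - ring_length_mm / 2
    s1 = rig.arc_position_mm + ring_length_mm / 2
    s0c, s1c = max(s0, 0.0), min(s1, cl.length)
    if resolution is None:
        resolution = (max(int(round(2 * (s1c - s0c))), 2), 360)
    n_rows, n_cols = resolution

    az = (np.arange(n_cols) + 0.5) * (360.0 / n_cols)
    arcs = np.linspace(s0c, s1c, n_rows)
    faces = mesh.faces
    verts = mesh.vertices

    # candidate faces: centroid within the ring arc interval (with margin)
    # and within reach of the rig
    from scipy.spatial import cKDTree

    cl_tree = cKDTree(cl.points)
    centroids = verts[faces].mean(axis=1)
    d_near, idx_near = cl_tree.query(centroids, workers=-1)
    face_arc = cl.arc_length[idx_near]
    margin = 3.0
    cand = ((face_arc >= s0c - margin) & (face_arc <= s1c + margin)
            & (d_near <= rig.far_mm))
    cand_idx = np.flatnonzero(cand)
    if cand_idx.size == 0:
        raise ValueError("no mesh faces within the requested ring")
    tri_v = verts[faces[cand_idx]]
    tri = (tri_v[:, 0], tri_v[:, 1] - tri_v[:, 0], tri_v[:, 2] - tri_v[:, 0])
    cand_arc = face_arc[cand_idx]
    # per-row face reach: faces can extend away from their centroid arc
    face_extent = np.linalg.norm(tri_v - tri_v.mean(axis=1, keepdims=True),
                                 axis=2).max() if len(tri_v) else 1.0
    row_margin = float(face_extent) + 1.0

    # lumen containment check: the rig center must see a wall in front of
    # and behind it along the frame normal
    probe_f, probe_t = _ray_cast_rows(
        np.vstack([rig.center, rig.center]),
        np.vstack([rig.frame_normal, -rig.frame_normal]), tri, rig.near_mm * 0.1)
    if (probe_f < 0).any():
        raise ValueError("camera rig is not inside the lumen (no wall on both sides)")

    cell_map = np.full((n_rows, n_cols), -1, dtype=np.int64)
    dist = np.full((n_rows, n_cols), np.inf)
    raydirs = np.empty((n_rows, n_cols, 3))
    cos_az, sin_az = np.cos(np.deg2rad(az)), np.sin(np.deg2rad(az))
    for i, s in enumerate(arcs):
        p, t, n, b = cl.frame_at(s)
        dirs = cos_az[:, None] * n + sin_az[:, None] * b
        origins = np.broadcast_to(p, (n_cols, 3))
        near_row = np.flatnonzero(np.abs(cand_arc - s) <= row_margin)
        row_tri = (tri[0][near_row], tri[1][near_row], tri[2][near_row])
        f_idx, f_t = _ray_cast_rows(np.ascontiguousarray(origins), dirs, row_tri, rig.near_mm)
        hit = f_idx >= 0
        cell_map[i, hit] = cand_idx[near_row[f_idx[hit]]]
        dist[i] = f_t
        raydirs[i] = dirs

    hit = cell_map >= 0
    # visibility factors: ray direction is the projection direction p
    cam = rig.camera_of_azimuth(az)
    look = rig.looks[cam]                      # (cols, 3)
    cosa = np.einsum("rcx,cx->rc", raydirs, look)
    alpha = np.arccos(np.clip(cosa, -1, 1))
    # face normals on the lumen side
    if mesh.normals is not None:
        fnorm = mesh.normals[faces].mean(axis=1)
        fnorm /= np.linalg.norm(fnorm, axis=1, keepdims=True).clip(1e-12)
    else:
        tmn = mesh.as_trimesh()
        fnorm = np.asarray(tmn.face_normals)
    pix_norm = np.zeros((n_rows, n_cols, 3))
    pix_norm[hit] = fnorm[cell_map[hit]]
    # phi: angle between the direction surface->camera (-ray) and the normal
    cosphi = np.einsum("rcx,rcx->rc", -raydirs, pix_norm)
    phi = np.arccos(np.clip(cosphi, -1, 1))
    d_safe = np.where(hit, dist, 1.0)
    loss = visualization_loss(alpha, phi, rig.focal_length_mm, d_safe)
    loss[~hit] = 1.0
    vis = VisCellScore(alpha=alpha, phi=phi, distance=np.where(hit, dist, np.nan),
                       loss=loss, flagged=loss > visibility_cutoff)

    # base shading: Lambertian toward the camera
    shade = np.clip(cosphi, 0.0, 1.0)
    shade[~hit] = 0.0
    rgb = np.repeat(shade[:, :, None], 3, axis=2)
    return FiletImage(rgb=rgb, cell_map=cell_map, ring_range=(s0c, s1c),
                      azimuth_deg=az, arc_mm=arcs, vis=vis)


def fuse_curvature(filet: FiletImage, mesh: SurfaceMesh,
                   range_mm_inv: float = 0.5) -> FiletImage:
    """Replace pixel colors by the curvature colormap of the underlying cell.

    Idempotent: re-fusing recomputes the same colors from the cell map.
    """
    if mesh.curvature is None:
        raise ValueError("mesh curvature missing; run compute_vertex_curvature")
    face_curv = mesh.face_curvature()
    hit = filet.cell_map >= 0
    curv = np.zeros(filet.shape)
    curv[hit] = face_curv[filet.cell_map[hit]]
    rgb = curvature_to_rgb(curv, range_mm_inv)
    rgb[~hit] = 0.0
    filet.rgb = rgb
    filet.curvature = np.where(hit, curv, 0.0)
    filet.curvature_range = range_mm_inv
    return filet


def project_annotations(truth: GroundTruth | list[PolypAnnotation],
                        filet: FiletImage, mesh: SurfaceMesh,
                        reach_factor: float = 1.3) -> FiletImage:
    """Attach tight pixel bounding boxes of each visible polyp.

    A polyp is visible when surface cells within ``reach_factor`` times its
    radius of its center appear in the filet's cell map; the box encloses
    exactly those pixels (wrap-aware: a polyp straddling the 0/360 azimuth
    seam gets one box whose column span wraps modulo the image width).
    Polyps outside the ring produce no box.
    """
    from .detect import wrap_box_from_pixels

    annotations = truth.polyp_annotations if isinstance(truth, GroundTruth) else truth
    centroids = mesh.face_centroids
    width = filet.cell_map.shape[1]
    filet.boxes = []
    for pid, ann in enumerate(annotations):
        center = np.asarray(ann.center_mm)
        near_faces = np.flatnonzero(
            np.linalg.norm(centroids - center, axis=1) <= reach_factor * ann.radius_mm)
        if near_faces.size == 0:
            continue
        member = np.isin(filet.cell_map, near_faces)
        if not member.any():
            continue
        rows, cols = np.nonzero(member)
        filet.boxes.append((pid, wrap_box_from_pixels(rows, cols, width)))
    return filet


def sweep_rings(mesh: SurfaceMesh, centerline: Centerline,
                step_mm: float = 10.0, ring_length_mm: float = 20.0,
                k: int = 8, focal_length_mm: float = 10.0,
                truth: GroundTruth | list[PolypAnnotation] | None = None,
                fuse: bool = True, resolution: tuple[int, int] | None = None,
                curvature_range: float = 0.5) -> list[FiletImage]:
    """Render overlapping rings covering the whole centerline.

    Ring centers advance by ``step_mm``; with the default 50% overlap every
    surface cell appears in at least one frame and no polyp can fall
    between rings.
    """
    if step_mm <= 0 or ring_length_mm <= 0:
        raise ValueError("step_mm and ring_length_mm must be positive")
    length = centerline.length
    half = ring_length_mm / 2
    if length <= ring_length_mm:
        centers = [length / 2]
    else:
        centers = list(np.arange(half, length - half + 1e-9, step_mm))
        if centers[-1] < length - half - 1e-6:
            centers.append(length - half)
    frames = []
    for s in centers:
        rig = build_rig(centerline, float(s), k=k, focal_length_mm=focal_length_mm)
        filet = render_filet(mesh, rig, ring_length_mm, resolution=resolution)
        if fuse:
            filet = fuse_curvature(filet, mesh, curvature_range)
        if truth is not None:
            filet = project_annotations(truth, filet, mesh)
        frames.append(filet)
    return frames


def save_filet_png(filet: FiletImage, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.clip(filet.rgb, 0, 1) * 255).astype(np.uint8))
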