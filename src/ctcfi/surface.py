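"""Luminal surface reconstruction, centerline extraction and curvature.

The colon surface is triangulated from the binary colon mask by marching
cubes, with vertex normals oriented into the lumen (toward the air the
virtual cameras sit in).  A centerline — the medial path the camera rig
advances along — is extracted as a distance-transform-weighted shortest
path between the two geodesically farthest lumen voxels, then smoothed.
Per-vertex mean curvature H = (k1 + k2) / 2 is estimated by local quadric
fitting; the sign convention makes lumen-protruding geometry (polyps)
positive, so polyps land on one pole of the diverging colormap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .geometry import (
    cumulative_arc_length,
    parallel_transport_frames,
    path_tangents,
    resample_path,
)


@dataclass
class SurfaceMesh:
    """Triangulated luminal surface in physical mm.

    ``normals`` are unit per-vertex normals oriented into the lumen (air
    side); ``curvature`` is per-vertex mean curvature in 1/mm, filled by
    :func:`compute_vertex_curvature` (protrusions into the lumen positive).
    """

    vertices: np.ndarray            # (nv, 3) mm
    faces: np.ndarray               # (nf, 3) int
    normals: np.ndarray | None = None
    curvature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_curvature(self) -> np.ndarray:
        if self.curvature is None:
            raise ValueError("curvature not computed; call compute_vertex_curvature first")
        return self.curvature[self.faces].mean(axis=1)


@dataclass
class Centerline:
    """Ordered medial path with arc length and transported frames."""

    points: np.ndarray              # (n, 3) mm
    tangents: np.ndarray = field(default=None)
    arc_length: np.ndarray = field(default=None)
    frames: tuple[np.ndarray, np.ndarray, np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.tangents is None or self.frames is None:
            t, n, b = parallel_transport_frames(self.points)
            self.tangents, self.frames = t, (t, n, b)
        if self.arc_length is None:
            self.arc_length = cumulative_arc_length(self.points)

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def frame_at(self, s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (point, tangent, normal, binormal) at arc position s mm."""
        s = float(np.clip(s, 0.0, self.length))
        i = int(np.searchsorted(self.arc_length, s).clip(1, len(self.points) - 1))
        s0, s1 = self.arc_length[i - 1], self.arc_length[i]
        w = 0.0 if s1 == s0 else (s - s0) / (s1 - s0)
        p = (1 - w) * self.points[i - 1] + w * self.points[i]
        t_, n_, b_ = self.frames

        def lerp_unit(a, b):
            v = (1 - w) * a + b * w
            return v / np.linalg.norm(v)

        t = lerp_unit(t_[i - 1], t_[i])
        n = lerp_unit(n_[i - 1], n_[i])
        n = n - np.dot(n, t) * t
        n /= np.linalg.norm(n)
        return p, t, n, np.cross(t, n)

    def to_json_dict(self) -> dict:
        return {
            "points_mm": self.points.tolist(),
            "arc_length_mm": self.arc_length.tolist(),
        }


def reconstruct_surface(mask: np.ndarray, spacing: tuple[float, float, float],
                        smooth_voxels: float = 1.0) -> SurfaceMesh:
    """Iso-surface the colon mask boundary at physical scale.

    Parameters
    ----------
    mask : 3-D bool array, (z, y, x)
        Lumen voxels (air side) are True.
    spacing : (dz, dy, dx) mm

    Returns a mesh in mm with per-vertex normals oriented into the lumen.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot reconstruct a surface from an empty mask")
    from skimage.measure import marching_cubes

    padded = np.pad(mask, 1).astype(np.float32)  # close surfaces at the boundary
    if smooth_voxels > 0:
        # smoothing the indicator field removes the staircase facets of a
        # binary iso-surface (which inflate area ~10%) and conditions the
        # mesh for curvature estimation
        padded = ndimage.gaussian_filter(padded, smooth_voxels)
    verts, faces, norms, _ = marching_cubes(
        padded, level=0.5, spacing=spacing,
        gradient_direction="ascent",
    )
    verts = verts - np.asarray(spacing)  # undo pad offset
    # mm coordinates in (z, y, x) axis order -> keep consistent (z, y, x)
    mesh = SurfaceMesh(verts, faces)
    tm = mesh.as_trimesh()
    vn = np.asarray(tm.vertex_normals, dtype=np.float64).copy()
    # orient into the lumen: normals should point toward mask=1 voxels
    interior = ndimage.binary_erosion(mask)
    probe = verts + vn * (0.75 * min(spacing))
    idx = np.round(probe / np.asarray(spacing)).astype(int)
    np.clip(idx, 0, np.asarray(mask.shape) - 1, out=idx)
    inside = mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    if inside.mean() < 0.5:
        vn = -vn
        mesh.faces = mesh.faces[:, ::-1].copy()
    norms_len = np.linalg.norm(vn, axis=1, keepdims=True)
    norms_len[norms_len == 0] = 1.0
    mesh.normals = vn / norms_len
    del interior
    return mesh


def _lumen_graph(mask: np.ndarray, spacing, weights: np.ndarray | None = None):
    """26-connected sparse graph over True voxels with Euclidean edge
    lengths (so geodesic distances approximate Euclidean ones); returns
    (graph, index_volume, coords)."""
    coords = np.argwhere(mask)
    index = -np.ones(mask.shape, dtype=np.int64)
    index[mask] = np.arange(len(coords))
    offsets = [np.array(o) for o in
               ((0, 0, 1), (0, 1, -1), (0, 1, 0), (0, 1, 1),
                (1, -1, -1), (1, -1, 0), (1, -1, 1), (1, 0, -1), (1, 0, 0),
                (1, 0, 1), (1, 1, -1), (1, 1, 0), (1, 1, 1))]
    sp = np.asarray(spacing, dtype=np.float64)
    rows, cols, data = [], [], []
    for off in offsets:
        a = coords
        b = coords + off
        ok = np.all((b >= 0) & (b < np.asarray(mask.shape)), axis=1)
        a, b = a[ok], b[ok]
        ok2 = mask[b[:, 0], b[:, 1], b[:, 2]]
        a, b = a[ok2], b[ok2]
        ia = index[a[:, 0], a[:, 1], a[:, 2]]
        ib = index[b[:, 0], b[:, 1], b[:, 2]]
        step = float(np.linalg.norm(off * sp))
        if weights is None:
            w = np.full(len(ia), step)
        else:
            w = step * 0.5 * (weights[a[:, 0], a[:, 1], a[:, 2]] + weights[b[:, 0], b[:, 1], b[:, 2]])
        rows.append(ia)
        cols.append(ib)
        data.append(w)
    rows = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
    data = np.concatenate(data) if data else np.array([])
    n = len(coords)
    g = sparse.csr_matrix((np.concatenate([data, data]),
                           (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                          shape=(n, n))
    return g, index, coords


def extract_centerline(mask: np.ndarray, spacing: tuple[float, float, float],
                       smooth_step_mm: float = 2.0) -> Centerline:
    """Medial path through a tubular mask.

    The two end points are found by a double geodesic sweep (farthest voxel
    from an arbitrary start, then farthest from that). The path between them
    is the shortest path where the cost of a step is weighted by the inverse
    squared distance-to-wall, which pins it to the medial axis. The voxel
    path is then spline-smoothed and resampled.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    # keep the largest connected component only
    lab, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))

    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    graph, index, coords = _lumen_graph(mask, spacing)
    if len(coords) < 3:
        raise ValueError("mask too small for centerline extraction")

    edt_flat = edt[mask]
    start = int(np.argmax(edt_flat))  # a deep voxel as sweep origin
    d0 = dijkstra(graph, indices=start, directed=False)
    if not np.isfinite(d0).all():
        raise ValueError("mask is not connected")

    def deep_far_voxel(dist_field):
        # the far set is a rim ring around the tube opening; its centroid
        # sits on the axis, so snap to the lumen voxel nearest the centroid
        # (over all lumen voxels) to get an on-axis end point
        far = dist_field >= 0.95 * dist_field.max()
        centroid = coords[far].mean(axis=0)
        return int(np.argmin(np.linalg.norm(coords - centroid, axis=1)))

    e1 = deep_far_voxel(d0)
    d1 = dijkstra(graph, indices=e1, directed=False)
    e2 = deep_far_voxel(d1)
    d2 = dijkstra(graph, indices=e2, directed=False)
    e1 = deep_far_voxel(d2)
    if e1 == e2:
        raise ValueError("mask is not tubular: no two distinct end points found")

    # medial weighting: steps through near-wall voxels are expensive
    w = 1.0 / (edt + 0.25 * min(spacing)) ** 2
    wgraph, _, _ = _lumen_graph(mask, spacing, weights=w)
    _, pred = dijkstra(wgraph, indices=e1, directed=False, return_predecessors=True)
    path_idx = []
    node = e2
    while node != e1 and node >= 0:
        path_idx.append(node)
        node = pred[node]
    if node != e1:
        raise ValueError("no path between end points")
    path_idx.append(e1)
    voxel_path = coords[np.array(path_idx[::-1])]
    sp = np.asarray(spacing, dtype=np.float64)
    mm_path = voxel_path * sp
    mm_path = _medialize(mm_path, coords * sp, float(edt.max()), sp, mask=mask)
    smooth = resample_path(_moving_average(mm_path, 9), smooth_step_mm)
    return Centerline(points=smooth)


def _medialize(mm_path, lumen_mm, r_max, spacing, step_mm=1.0, mask=None):
    """Pull a rough path onto the tube's medial axis by slab-centroid passes.

    Each path point is moved (laterally only) to the centroid of the lumen
    voxels in a thin slab perpendicular to the local tangent, searched
    within ~2 maximal radii; the ends are then marched outward along the
    local tangent, recentring each new point, until the cross-section
    collapses at the tube opening.  The search ball assumes the tube does
    not fold back on itself within about two radii (gentle curvature).
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(lumen_mm)
    radius = 2.2 * max(r_max, 2.0 * float(spacing.max()))
    slab = 0.8 * float(spacing.max())

    def slab_points(p, t):
        near = tree.query_ball_point(p, radius)
        if not near:
            return np.empty((0, 3))
        pts = lumen_mm[near]
        return pts[np.abs((pts - p) @ t) <= slab]

    path = resample_path(_moving_average(mm_path, 9), step_mm)
    for _ in range(3):
        tangents = path_tangents(path)
        new = path.copy()
        for i, (p, t) in enumerate(zip(path, tangents)):
            pts = slab_points(p, t)
            if len(pts) < 3:
                continue
            shift = pts.mean(axis=0) - p
            shift -= (shift @ t) * t
            new[i] = p + shift
        path = new

    def inside(pt):
        if mask is None:
            return False
        idx = np.round(pt / spacing).astype(int)
        if (idx < 0).any() or (idx >= np.asarray(mask.shape)).any():
            return False
        return bool(mask[idx[0], idx[1], idx[2]])

    for _ in range(2):  # extend each end, reversing between passes
        # the last ~radius of the path is biased by slab truncation at the
        # tube opening: drop it and re-cover it with a straight march along
        # a tangent taken from the clean interior (no recentring, so the
        # extension cannot crawl around a bend)
        k_trim = int(round(r_max / step_mm))
        if len(path) > 4 * k_trim:
            path = path[k_trim:]
        t = path[0] - path[min(10, len(path) - 1)]
        t /= max(np.linalg.norm(t), 1e-12)
        ext = []
        p = path[0]
        while len(ext) < int(3 * r_max / step_mm):
            q = p + t * step_mm
            if not inside(q):
                break
            ext.append(q)
            p = q
        if ext:
            path = np.vstack([np.array(ext[::-1]), path])
        path = path[::-1]
    return path


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    if len(points) <= window:
        return points
    kernel = np.ones(window) / window
    out = points.copy()
    for c in range(3):
        out[:, c] = np.convolve(np.pad(points[:, c], window // 2, mode="edge"),
                                kernel, mode="valid")[: len(points)]
    return out


def compute_vertex_curvature(mesh: SurfaceMesh, ring: int = 2) -> SurfaceMesh:
    """Per-vertex mean curvature (1/mm) by local quadric fitting.

    For each vertex a quadric z = ax^2 + bxy + cy^2 + dx + ey is fitted to
    its 2-ring neighborhood in the frame whose z axis is the (lumen-facing)
    vertex normal; the mean curvature is a + c. With inward normals this
    makes polyp-like protrusions positive and the concave colon wall, seen
    from inside, negative.
    """
    if mesh.normals is None:
        tm = mesh.as_trimesh()
        mesh.normals = np.asarray(tm.vertex_normals, dtype=np.float64)
    nv = len(mesh.vertices)
    # vertex adjacency
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    adj = sparse.csr_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(nv, nv))
    adj = ((adj + adj.T) > 0).astype(np.int8)
    reach = adj
    for _ in range(ring - 1):
        reach = ((reach @ adj) + reach) > 0
    reach = sparse.csr_matrix(reach)
    deg = np.diff(adj.indptr)
    if np.any(deg == 0):
        raise ValueError("mesh has isolated vertices")

    H = np.zeros(nv)
    indptr, indices = reach.indptr, reach.indices
    V, N = mesh.vertices, mesh.normals
    for i in range(nv):
        nbrs = indices[indptr[i]: indptr[i + 1]]
        nbrs = nbrs[nbrs != i]
        if len(nbrs) < 5:
            H[i] = np.nan
            continue
        n = N[i]
        # local tangent frame
        ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = ref - np.dot(ref, n) * n
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        rel = V[nbrs] - V[i]
        x = rel @ u
        y = rel @ v
        z = rel @ n
        A = np.column_stack([x * x, x * y, y * y, x, y])
        coef, *_ = np.linalg.lstsq(A, z, rcond=None)
        # with z along the lumen-side normal, protrusions into the lumen
        # have neighbors at negative height: negate so they come out positive
        H[i] = -(coef[0] + coef[2])
    # fill failed fits with neighborhood average
    bad = np.isnan(H)
    if bad.any():
        H[bad] = 0.0
    mesh.curvature = H
    return mesh


def curvature_to_rgb(curvature: np.ndarray, range_mm_inv: float = 0.5) -> np.ndarray:
    """Diverging curvature colormap.

    Zero curvature maps to neutral gray (0.5, 0.5, 0.5); positive values
    (protrusions) push the red channel up, negative push blue up; values are
    clamped at +/- range.  Each channel is monotone in curvature, and the
    map is injective on (-range, +range); it is inverted exactly by
    :func:`rgb_to_curvature` (H = (R - B) * range).
    """
    if range_mm_inv <= 0:
        raise ValueError("range_mm_inv must be positive")
    u = np.clip(np.asarray(curvature, dtype=np.float64) / range_mm_inv, -1.0, 1.0)
    r = 0.5 + 0.5 * u
    b = 0.5 - 0.5 * u
    g = np.full_like(u, 0.5)
    return np.stack([r, g, b], axis=-1)


def rgb_to_curvature(rgb: np.ndarray, range_mm_inv: float = 0.5) -> np.ndarray:
    """Exact inverse of :func:`curvature_to_rgb` inside the clamp range."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return (rgb[..., 0] - rgb[..., 2]) * range_mm_inv


def save_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write PLY (with normal + curvature vertex attributes) or STL."""
    path = Path(path)
    tm = mesh.as_trimesh()
    if path.suffix.lower() == ".ply":
        if mesh.normals is not None:
            tm.vertex_normals = mesh.normals
        if mesh.curvature is not None:
            tm.vertex_attributes["curvature"] = mesh.curvature.astype(np.float32)
        tm.export(str(path), encoding="binary")
    elif path.suffix.lower() == ".stl":
        tm.export(str(path))
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix}")


def load_mesh(path: str | Path) -> SurfaceMesh:
    tm = trimesh.load(str(path), process=False)
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    curv = tm.vertex_attributes.get("curvature") if hasattr(tm, "vertex_attributes") else None
    if curv is not None:
        mesh.curvature = np.asarray(curv, dtype=np.float64)
    mesh.normals = np.asarray(tm.vertex_normals, dtype=np.float64)
    return mesh
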