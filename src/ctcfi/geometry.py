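"""Shared path-geometry helpers: spline resampling and frame transport."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def resample_path(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Interpolate ordered 3-D points with a C2 cubic spline and resample
    at (approximately) uniform arc-length steps.

    Parameters
    ----------
    points : (n, 3) array
        Ordered control points in mm. n >= 2.
    step_mm : float
        Target spacing between output samples.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ValueError("need an (n>=2, 3) array of control points")
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    # chord-length parametrisation
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg == 0):
        keep = np.concatenate([[True], seg > 0])
        points = points[keep]
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if len(points) == 2:
        n = max(int(np.ceil(t[-1] / step_mm)) + 1, 2)
        u = np.linspace(0, 1, n)[:, None]
        return points[0] * (1 - u) + points[1] * u
    spline = CubicSpline(t, points, axis=0)
    # oversample, then re-measure arc length for near-uniform spacing
    dense_t = np.linspace(t[0], t[-1], max(len(t) * 32, 256))
    dense = spline(dense_t)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    n = max(int(np.ceil(arc[-1] / step_mm)) + 1, 2)
    targets = np.linspace(0, arc[-1], n)
    return dense[np.searchsorted(arc, targets).clip(0, len(dense) - 1)]


def path_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents of an ordered polyline by central differences."""
    points = np.asarray(points, dtype=np.float64)
    tan = np.gradient(points, axis=0)
    norms = np.linalg.norm(tan, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return tan / norms


def parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (tangent, normal, binormal) frames along a polyline.

    The normal is propagated by parallel transport (rotation taking each
    tangent to the next), which avoids the sudden frame flips of the Frenet
    frame at inflection points and gives a stable azimuth coordinate.
    """
    points = np.asarray(points, dtype=np.float64)
    tangents = path_tangents(points)
    n_pts = len(points)
    normals = np.empty_like(tangents)
    # initial normal: any unit vector orthogonal to the first tangent
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0]) if abs(t0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n0 = ref - np.dot(ref, t0) * t0
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(1, n_pts):
        a, b = tangents[i - 1], tangents[i]
        v = np.cross(a, b)
        s = np.linalg.norm(v)
        c = float(np.dot(a, b))
        if s < 1e-12:
            n = normals[i - 1]
        else:
            # Rodrigues rotation of the previous normal about axis v by the
            # angle between consecutive tangents
            k = v / s
            n_prev = normals[i - 1]
            n = n_prev * c + np.cross(k, n_prev) * s + k * np.dot(k, n_prev) * (1 - c)
        n = n - np.dot(n, b) * b
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=np.float64)
    return np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
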