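"""Low-level vector/frame helpers shared by anatomy, meshing and masks.

Conventions used package-wide:

* All lengths are millimetres.
* Centerlines are ordered proximal (cranial) to distal; tangents point distal.
* The circumferential angle ``phi`` of a point around the vessel axis is
  measured from a datum vector projected into the cross-sectional plane,
  *clockwise as seen from the proximal side looking distally*.  With the
  tangent ``t`` pointing distal this is the right-handed angle about ``t``:
  looking along +t, a right-handed rotation appears clockwise to a proximal
  observer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "project_out",
    "signed_angle_about",
    "circumferential_direction",
    "rotation_minimizing_normals",
    "dist_points_to_segments",
    "wrap_difference",
]


def unit(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalize vectors along ``axis``; raises on zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def project_out(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Component of ``v`` orthogonal to unit vector ``t``."""
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    return v - np.dot(v, t) * t


def signed_angle_about(t: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Angle (degrees, in [0, 360)) from ``a`` to ``b`` about unit axis ``t``.

    Right-handed about ``t``; with ``t`` pointing distal this is the
    clockwise-from-proximal surgical convention for ``phi``.
    """
    ang = np.degrees(np.arctan2(np.dot(t, np.cross(a, b)), np.dot(a, b)))
    return float(np.mod(ang, 360.0))


def circumferential_direction(t: np.ndarray, datum_in_plane: np.ndarray, phi_deg: float) -> np.ndarray:
    """Unit direction at angle ``phi`` (degrees) from the in-plane datum.

    Inverse of :func:`signed_angle_about` for unit in-plane inputs:
    ``signed_angle_about(t, d, circumferential_direction(t, d, phi)) == phi``.
    """
    phi = np.radians(phi_deg)
    return np.cos(phi) * datum_in_plane + np.sin(phi) * np.cross(t, datum_in_plane)


def rotation_minimizing_normals(points: np.ndarray, tangents: np.ndarray,
                                n0: np.ndarray | None = None) -> np.ndarray:
    """Propagate a normal along a polyline with the double-reflection method.

    Produces a twist-free moving frame (used as a fallback frame where the
    global datum vector degenerates against the tangent).
    """
    points = np.asarray(points, dtype=float)
    tangents = unit(np.asarray(tangents, dtype=float))
    n = np.empty_like(points)
    if n0 is None:
        # any vector not parallel to t0
        trial = np.array([0.0, 1.0, 0.0])
        if abs(np.dot(trial, tangents[0])) > 0.9:
            trial = np.array([1.0, 0.0, 0.0])
        n0 = project_out(trial, tangents[0])
    n[0] = unit(n0 - np.dot(n0, tangents[0]) * tangents[0])
    for i in range(len(points) - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-16:
            n[i + 1] = n[i]
            continue
        nL = n[i] - (2.0 / c1) * np.dot(v1, n[i]) * v1
        tL = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 < 1e-16:
            n[i + 1] = nL
        else:
            n[i + 1] = nL - (2.0 / c2) * np.dot(v2, nL) * v2
        n[i + 1] = unit(project_out(n[i + 1], tangents[i + 1]))
    return n


def dist_points_to_segments(points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray,
                            chunk: int = 20000) -> np.ndarray:
    """Minimum Euclidean distance from each 2D/3D point to a set of segments.

    Vectorized point-to-segment distance, chunked over points to bound
    memory (P x S temporaries).
    """
    points = np.asarray(points, dtype=float)
    seg_a = np.asarray(seg_a, dtype=float)
    seg_b = np.asarray(seg_b, dtype=float)
    d = seg_b - seg_a                      # (S, k)
    dd = np.einsum("sk,sk->s", d, d)
    dd = np.where(dd < 1e-18, 1.0, dd)     # degenerate segments -> treated as points
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk]          # (P, k)
        ap = p[:, None, :] - seg_a[None, :, :]           # (P, S, k)
        t = np.clip(np.einsum("psk,sk->ps", ap, d) / dd, 0.0, 1.0)
        closest = seg_a[None, :, :] + t[:, :, None] * d[None, :, :]
        diff = p[:, None, :] - closest
        out[lo:lo + chunk] = np.sqrt(np.einsum("psk,psk->ps", diff, diff).min(axis=1))
    return out


def wrap_difference(a: float | np.ndarray, b: float | np.ndarray, period: float) -> np.ndarray:
    """Signed difference ``a - b`` wrapped onto the shorter arc (-period/2, period/2]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), period)
    return np.where(d > period / 2.0, d - period, d)
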