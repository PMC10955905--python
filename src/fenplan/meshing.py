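"""Deployed-graft surface construction.

Three steps: fit a smoothing spline through the aortic cross-section
centroids, size the deployed graft diameter from the proximal landing zone
(the first 10% of graft length, where the fabric must seal against healthy
wall with an interference fit), and sweep ("loft") a structured cylindrical
triangle mesh along the spline.  The lofted tube is cut open along the
phi = 0 datum generator so that it is a topological disk, which the
parameterization stage flattens onto a rectangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .errors import InputError, MeshError, ParameterError
from .geometry import (circumferential_direction, project_out,
                       rotation_minimizing_normals, unit)

__all__ = [
    "CenterlineSpline",
    "GraftMesh",
    "fit_centerline_spline",
    "size_graft_diameter",
    "deployed_profile",
    "loft_mesh",
]

#: fraction of graft length defining the proximal landing zone
LANDING_ZONE_FRACTION = 0.10


class CenterlineSpline:
    """C2 smoothing spline through 3D points, reparameterized by arclength.

    ``point(s)``, ``tangent(s)`` and ``curvature(s)`` take arclength in mm
    from the proximal end.  The arclength reparameterization is tabulated on
    a dense grid; its relative error is well below 0.1% for the densities
    used here.
    """

    def __init__(self, points: np.ndarray, smoothing: float | None = None,
                 n_dense: int = 4000):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise InputError("centerline points must be an (N, 3) array")
        # drop duplicate consecutive points
        keep = np.ones(len(points), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-9
        if not keep.all():
            warnings.warn("duplicate consecutive centerline points removed")
            points = points[keep]
        if len(points) < 4:
            raise InputError("need at least 4 distinct points to fit a centerline spline")
        if smoothing is None:
            smoothing = len(points) * 0.2 ** 2  # ~0.2 mm residual scale
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
        u = chord / chord[-1]
        k = min(3, len(points) - 1)
        self._tck, _ = interpolate.splprep(points.T, u=u, s=smoothing, k=k)
        uu = np.linspace(0.0, 1.0, n_dense)
        xyz = np.array(interpolate.splev(uu, self._tck)).T
        seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(s[-1])
        self._u_of_s = interpolate.interp1d(s, uu, kind="linear", bounds_error=False,
                                            fill_value=(0.0, 1.0))

    def _u(self, s):
        return self._u_of_s(np.clip(s, 0.0, self.length))

    def point(self, s) -> np.ndarray:
        """Position at arclength ``s`` (mm); vectorized."""
        out = np.array(interpolate.splev(self._u(s), self._tck)).T
        return out

    def tangent(self, s) -> np.ndarray:
        d = np.array(interpolate.splev(self._u(s), self._tck, der=1)).T
        return unit(d)

    def curvature(self, s) -> np.ndarray:
        u = self._u(s)
        d1 = np.array(interpolate.splev(u, self._tck, der=1)).T
        d2 = np.array(interpolate.splev(u, self._tck, der=2)).T
        num = np.linalg.norm(np.cross(d1, d2), axis=-1)
        den = np.linalg.norm(d1, axis=-1) ** 3
        return num / den


def fit_centerline_spline(points: np.ndarray, smoothing: float | None = None) -> CenterlineSpline:
    """Smoothing spline of best fit through ordered centerline points.

    ``smoothing`` is the scipy ``splprep`` residual budget; the default
    assumes ~0.2 mm centroid noise.  Use ``n * sigma**2`` for noisier data.
    """
    return CenterlineSpline(points, smoothing=smoothing)


def size_graft_diameter(centerline, template, graft_top_station: float) -> float:
    """Deployed graft diameter from the proximal landing zone.

    The deployed diameter is the mean lumen diameter over the landing zone
    — the first 10% of graft length distal of the graft top — capped at the
    template's nominal proximal diameter (fabric cannot expand beyond its
    manufactured size).  When the aorta is narrower than nominal, the
    oversized fabric conforms to the wall (interference fit), so the
    deployed diameter equals the wall diameter.
    """
    lz_end = graft_top_station + LANDING_ZONE_FRACTION * template.length
    if graft_top_station < -1e-9 or lz_end > centerline.length + 1e-9:
        raise InputError("landing zone extends outside the centerline")
    s = np.linspace(graft_top_station, lz_end, 64)
    mean_d = float(np.mean(centerline.diameter_at(s)))
    return min(mean_d, template.proximal_diameter)


def deployed_profile(centerline, template, graft_top_station: float,
                     stations: np.ndarray) -> np.ndarray:
    """Deployed diameter per axial station.

    Uniform grafts deploy at the landing-zone diameter everywhere.  Tapered
    grafts interpolate linearly between the proximal deployed diameter and a
    distal deployed diameter sized from the distal 10% of graft length
    (capped at the distal nominal); each station is additionally capped at
    the local nominal fabric diameter.
    """
    d_prox = size_graft_diameter(centerline, template, graft_top_station)
    if not template.tapered:
        return np.full(len(stations), d_prox)
    s_dist = np.linspace(graft_top_station + (1 - LANDING_ZONE_FRACTION) * template.length,
                         min(graft_top_station + template.length, centerline.length), 64)
    d_dist = min(float(np.mean(centerline.diameter_at(s_dist))), template.distal_diameter)
    f = np.clip((np.asarray(stations) - graft_top_station) / template.length, 0.0, 1.0)
    prof = d_prox + f * (d_dist - d_prox)
    return np.minimum(prof, template.nominal_diameter_at(f * template.length))


@dataclass
class GraftMesh:
    """Structured triangle mesh of the deployed graft tube, cut at the seam.

    Vertices form an (n_axial, n_circ + 1) grid; column 0 and column n_circ
    are geometrically coincident duplicates along the phi = 0 seam, so the
    mesh is a topological disk (one boundary loop, Euler characteristic 1).
    """

    vertices: np.ndarray               # (N, 3) mm
    faces: np.ndarray                  # (M, 3) int
    grid_shape: tuple[int, int]        # (n_axial, n_circ + 1)
    seam_vertices: np.ndarray = field(default=None)   # left seam column indices
    seam_vertices_right: np.ndarray = field(default=None)
    boundary_proximal: np.ndarray = field(default=None)
    boundary_distal: np.ndarray = field(default=None)
    stations: np.ndarray = field(default=None)        # arclength per axial row
    diameters: np.ndarray = field(default=None)       # deployed diameter per row

    @property
    def n_axial(self) -> int:
        return self.grid_shape[0]

    @property
    def n_circ(self) -> int:
        return self.grid_shape[1] - 1

    def vertex_index(self, i: int, j: int) -> int:
        return i * self.grid_shape[1] + j

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def euler_characteristic(self) -> int:
        edges = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return len(self.vertices) - len(edges) + len(self.faces)

    def to_trimesh(self):
        import trimesh
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def save_stl(self, path) -> None:
        self.to_trimesh().export(str(path))


def loft_mesh(spline, diameters, graft_top_station: float, length: float,
              n_axial: int = None, n_circ: int = 96, *,
              datum=(0.0, 1.0, 0.0)) -> GraftMesh:
    """Sweep a cylindrical graft mesh along the centerline spline.

    ``diameters`` is a scalar deployed diameter or a per-station array of
    length ``n_axial``.  Rings of ``n_circ`` vertices are placed at
    ``n_axial`` stations; within each cross-section, vertex ``j`` sits at
    phi = j * 360 / n_circ measured from the projected datum vector, so the
    seam (j = 0, duplicated at j = n_circ) lies on the datum generator and
    mesh AL coincides with mask AL.  Where the tangent is nearly parallel to
    the datum, the frame falls back to rotation-minimizing (twist-free)
    transport from the previous station.

    A warning is emitted when the centerline curvature radius drops below
    the graft radius (the loft locally self-intersects).
    """
    if n_axial is None:
        n_axial = max(4, int(np.ceil(length / 1.0)))
    if n_axial < 4 or n_circ < 8:
        raise ParameterError("need n_axial >= 4 and n_circ >= 8")
    datum = unit(np.asarray(datum, dtype=float))
    stations = graft_top_station + np.linspace(0.0, length, n_axial)
    centers = np.atleast_2d(spline.point(stations))
    tangents = np.atleast_2d(spline.tangent(stations))
    radii = np.broadcast_to(np.asarray(diameters, dtype=float), (n_axial,)) / 2.0

    # self-intersection check: curvature radius vs graft radius
    kappa = np.atleast_1d(spline.curvature(stations))
    bad = kappa * radii > 1.0
    if np.any(bad):
        warnings.warn(f"loft self-intersects at {int(bad.sum())} stations "
                      "(curvature radius < graft radius)")

    # per-station in-plane datum; RMF fallback where degenerate
    rmf = rotation_minimizing_normals(centers, tangents)
    normals = np.empty_like(centers)
    for i in range(n_axial):
        dp = project_out(datum, tangents[i])
        nrm = np.linalg.norm(dp)
        if nrm < 0.1:
            # near-degenerate: keep the twist-free transported direction
            prev = normals[i - 1] if i else rmf[i]
            normals[i] = unit(project_out(prev, tangents[i]))
        else:
            normals[i] = dp / nrm

    ncol = n_circ + 1
    phis = np.arange(ncol) * (360.0 / n_circ)  # phi[n_circ] = 360 -> seam duplicate
    verts = np.empty((n_axial * ncol, 3))
    for i in range(n_axial):
        dirs = np.array([circumferential_direction(tangents[i], normals[i], p) for p in phis])
        verts[i * ncol:(i + 1) * ncol] = centers[i] + radii[i] * dirs

    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * ncol + j
            b = i * ncol + j + 1
            c = (i + 1) * ncol + j
            d = (i + 1) * ncol + j + 1
            faces.append((a, b, c))
            faces.append((b, d, c))
    faces = np.asarray(faces, dtype=np.int64)

    mesh = GraftMesh(
        vertices=verts, faces=faces, grid_shape=(n_axial, ncol),
        seam_vertices=np.arange(n_axial) * ncol,
        seam_vertices_right=np.arange(n_axial) * ncol + n_circ,
        boundary_proximal=np.arange(ncol),
        boundary_distal=(n_axial - 1) * ncol + np.arange(ncol),
        stations=stations, diameters=2.0 * radii,
    )
    _orient_outward(mesh, centers)
    if np.any(mesh.face_areas() <= 1e-9):
        raise MeshError("loft produced degenerate faces")
    return mesh


def _orient_outward(mesh: GraftMesh, centers: np.ndarray) -> None:
    """Flip all faces if their normals point into the tube (majority vote)."""
    v = mesh.vertices
    f = mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    centroids = v[f].mean(axis=1)
    # radial direction: centroid minus nearest station center
    ncol = mesh.grid_shape[1]
    row = (f[:, 0] // ncol)
    radial = centroids - centers[np.clip(row, 0, len(centers) - 1)]
    if np.sum(np.einsum("ij,ij->i", fn, radial) > 0) < len(f) / 2:
        mesh.faces = f[:, ::-1].copy()
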