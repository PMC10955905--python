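"""Barycentric texture mapping between the 2D design and the 3D graft.

Any point inside a triangle with 2D vertices (x1,y1), (x2,y2), (x3,y3) has
barycentric coordinates (l1, l2, l3), l1 + l2 + l3 = 1, obtained by
inverting the 2x2 edge matrix T:

    l1 = ((y2 - y3)(x - x3) - (x3 - x2)(y - y3)) / det(T)
    l2 = ((y3 - y1)(x - x3) - (x1 - x3)(y - y3)) / det(T)
    l3 = 1 - l1 - l2

Applying the same weights to the triangle's 3D vertices carries a point of
the flattened rectangle onto the graft surface; this is how fenestration
centers (and, pixel by pixel, the whole design image) are rendered in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FenPlanError, InputError, ValidationError
from .geometry import wrap_difference
from .masks import Mask2D
from .meshing import GraftMesh
from .parameterize import Parameterization

__all__ = [
    "barycentric_coords",
    "SurfaceMapper",
    "uv_to_surface",
    "alignment_deviation",
    "MappedDesign",
    "map_design",
]


def barycentric_coords(p, tri) -> tuple[float, float, float]:
    """Barycentric coordinates of 2D point ``p`` in triangle ``tri`` (3 x 2).

    Raises on degenerate triangles (det(T) = 0).  ``p`` lies inside or on
    the triangle iff all three coordinates are >= 0.
    """
    (x1, y1), (x2, y2), (x3, y3) = np.asarray(tri, dtype=float)
    x, y = float(p[0]), float(p[1])
    det = (x1 - x3) * (y2 - y3) - (x2 - x3) * (y1 - y3)
    if abs(det) < 1e-14:
        raise ValidationError("degenerate triangle: det(T) = 0")
    # lambda = T^-1 (p - r3), T = [[x1-x3, x2-x3], [y1-y3, y2-y3]]
    l1 = ((y2 - y3) * (x - x3) - (x2 - x3) * (y - y3)) / det
    l2 = ((x1 - x3) * (y - y3) - (y1 - y3) * (x - x3)) / det
    return l1, l2, 1.0 - l1 - l2


class SurfaceMapper:
    """Locates uv points in the flattened mesh and lifts them to 3D.

    A uniform-grid spatial index over the uv triangles accelerates the
    point-in-triangle query; an exhaustive scan is used as fallback (and is
    available for testing via ``exhaustive=True``).
    """

    def __init__(self, param: Parameterization, mesh: GraftMesh,
                 grid_cell: float | None = None, exhaustive: bool = False):
        self.param = param
        self.mesh = mesh
        self.exhaustive = exhaustive
        uv = param.uv
        f = mesh.faces
        self._tri_uv = uv[f]                       # (M, 3, 2)
        self._tri_xyz = mesh.vertices[f]           # (M, 3, 3)
        lo = self._tri_uv.min(axis=1)
        hi = self._tri_uv.max(axis=1)
        if grid_cell is None:
            grid_cell = float(np.median(hi - lo).max()) * 2.0 or 1.0
        self._cell = grid_cell
        self._index: dict[tuple[int, int], list[int]] = {}
        ilo = np.floor(lo / grid_cell).astype(int)
        ihi = np.floor(hi / grid_cell).astype(int)
        for fi in range(len(f)):
            for cx in range(ilo[fi, 0], ihi[fi, 0] + 1):
                for cy in range(ilo[fi, 1], ihi[fi, 1] + 1):
                    self._index.setdefault((cx, cy), []).append(fi)

    def _candidates(self, p) -> list[int]:
        if self.exhaustive:
            return list(range(len(self.mesh.faces)))
        c = (int(np.floor(p[0] / self._cell)), int(np.floor(p[1] / self._cell)))
        return self._index.get(c, [])

    def locate(self, p, tol: float = 1e-9) -> tuple[int, tuple[float, float, float]]:
        """Face index and barycentric coordinates of uv point ``p``."""
        best = None
        for cands in (self._candidates(p), range(len(self.mesh.faces))):
            for fi in cands:
                try:
                    lam = barycentric_coords(p, self._tri_uv[fi])
                except ValidationError:
                    continue
                worst = min(lam)
                if worst >= -tol:
                    return fi, lam
                if best is None or worst > best[0]:
                    best = (worst, fi, lam)
        # numerical gap between triangles: snap to the nearest face if the
        # point is within ~1e-6 mm of it
        if best is not None and best[0] > -1e-6:
            lam = np.clip(best[2], 0.0, None)
            lam = tuple(lam / lam.sum())
            return best[1], lam
        raise FenPlanError(f"uv point {tuple(p)} lies outside the parameterized rectangle")

    def to_3d(self, p) -> np.ndarray:
        """Lift uv point ``p`` = (AL, PGD) mm onto the 3D graft surface."""
        fi, lam = self.locate(p)
        return np.einsum("i,ij->j", np.asarray(lam), self._tri_xyz[fi])


def uv_to_surface(param: Parameterization, mesh: GraftMesh, p) -> np.ndarray:
    """One-shot wrapper around :class:`SurfaceMapper` for a single point."""
    return SurfaceMapper(param, mesh).to_3d(p)


def alignment_deviation(center_uv, truth_uv, al_period: float | None = None) -> float:
    """Curved-surface deviation delta = sqrt(dAL^2 + dPGD^2) in mm.

    With ``al_period`` given, the AL difference is taken on the shorter arc
    around the graft circumference.
    """
    dal = float(center_uv[0]) - float(truth_uv[0])
    if al_period is not None:
        dal = float(wrap_difference(dal, 0.0, al_period))
    dpgd = float(center_uv[1]) - float(truth_uv[1])
    return float(np.hypot(dal, dpgd))


@dataclass
class MappedDesign:
    """The fitted 2D design rendered on the 3D graft surface."""

    fen_centers_uv: dict[str, tuple[float, float]]
    fen_centers_3d: dict[str, np.ndarray]
    delta_f: dict[str, float]                  # deviation vs measured ostia, mm
    mesh: GraftMesh = None
    param: Parameterization = None
    design: Mask2D = None
    delta_m: dict[str, float] | None = None    # optional manual-plan deviations

    def vertex_design_values(self) -> np.ndarray:
        """Sample the design mask at every vertex uv (1 = strut/forbidden)."""
        if self.design is None:
            return np.zeros(len(self.mesh.vertices))
        res = self.design.resolution
        cols = np.clip((self.param.uv[:, 0] / res).astype(int), 0, self.design.n_cols - 1)
        rows = np.clip((self.param.uv[:, 1] / res).astype(int), 0, self.design.n_rows - 1)
        return self.design.pixels[rows, cols].astype(float)

    def save_obj(self, path, texture_png: str | None = None) -> None:
        """Write the textured mesh as OBJ with per-vertex uv texture coords."""
        from pathlib import Path

        path = Path(path)
        uv = self.param.uv / np.array([self.param.al_extent, self.param.pgd_extent])
        lines = ["# fenplan textured graft mesh"]
        if texture_png:
            mtl = path.with_suffix(".mtl")
            mtl.write_text("newmtl design\nmap_Kd %s\n" % Path(texture_png).name)
            lines.append(f"mtllib {mtl.name}")
            lines.append("usemtl design")
        for v in self.mesh.vertices:
            lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
        for t in uv:
            lines.append(f"vt {t[0]:.6f} {1.0 - t[1]:.6f}")
        for f in self.mesh.faces + 1:
            lines.append(f"f {f[0]}/{f[0]} {f[1]}/{f[1]} {f[2]}/{f[2]}")
        path.write_text("\n".join(lines) + "\n")


def map_design(fit, specs, param: Parameterization, mesh: GraftMesh,
               design: Mask2D | None = None, *, truth_uv: dict | None = None,
               force: bool = False) -> MappedDesign:
    """Render the fitted fenestration design onto the 3D graft surface.

    Each vessel's fitted center (its measured (AL, PGD) plus the global
    offsets plus any per-vessel relaxation) is located in the flattened
    rectangle and lifted through the shared triangle's 3D vertices.  The
    deviation ``delta_f`` compares the fitted center to the measured ostium
    position (``truth_uv`` overrides, e.g. with generator ground truth).
    """
    if not fit.valid and not force:
        raise InputError("fit is invalid; pass force=True to map it anyway")
    period = param.al_extent
    mapper = SurfaceMapper(param, mesh)
    centers_uv, centers_3d, delta = {}, {}, {}
    for sp in specs:
        shift_al, shift_pgd = fit.per_vessel_shift.get(sp.vessel, (0.0, 0.0))
        al = float(np.mod(sp.al + fit.dal + shift_al, period))
        pgd = sp.pgd + fit.dpgd + shift_pgd
        if not (0.0 <= pgd <= param.pgd_extent):
            raise FenPlanError(f"fitted center of vessel {sp.vessel} lies outside the graft")
        centers_uv[sp.vessel] = (al, pgd)
        # keep strictly inside the open rectangle for the triangle lookup
        p = (min(max(al, 1e-9), period - 1e-9),
             min(max(pgd, 1e-9), param.pgd_extent - 1e-9))
        centers_3d[sp.vessel] = mapper.to_3d(p)
        ref = (truth_uv or {}).get(sp.vessel, (sp.al, sp.pgd))
        delta[sp.vessel] = alignment_deviation((al, pgd), ref, al_period=period)
    return MappedDesign(fen_centers_uv=centers_uv, fen_centers_3d=centers_3d,
                        delta_f=delta, mesh=mesh, param=param, design=design)
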