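"""Parametric stent-graft templates and their flattened (unrolled) masks.

A commercial tube endograft is described by a handful of parameters: fabric
length, proximal/distal diameters, and the zigzag strut rings (amplitude =
peak-to-peak height, wire width, number of apices, axial ring positions).
Flattening unrolls the deployed graft surface into the (AL, PGD) plane and
rasterizes the strut wires — dilated by a configurable safety margin, since
the cautery tool cannot approach the metal closely — into a binary *graft
mask*.  Open fabric is 0, forbidden material is 1.

The strut pattern implemented here is a symmetric triangular zigzag with
alternating apices.  Commercial patterns vary by vendor; the bundled
repository entries are illustrative shapes, not vendor-certified drawings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import DescriptorError, ParameterError, ValidationError
from .geometry import dist_points_to_segments
from .masks import Mask2D

__all__ = [
    "GraftTemplate",
    "make_template",
    "flatten_uniform",
    "flatten_tapered",
    "flatten",
    "load_repository",
    "zigzag_segments",
]

#: default rasterization resolution, mm per pixel (sub-mm deviation
#: reporting requires sub-mm pixels)
DEFAULT_RESOLUTION = 0.25
#: default cautery safety margin added around the strut wire, mm
DEFAULT_MARGIN = 1.0


@dataclass(frozen=True)
class GraftTemplate:
    """Parametric description of a tube endograft."""

    name: str
    length: float                      # fabric length, mm
    proximal_diameter: float           # nominal manufactured diameter, mm
    distal_diameter: float
    strut_amplitude: float             # peak-to-peak zigzag height, mm
    strut_wire_width: float            # wire diameter, mm
    n_peaks_per_ring: int              # apices per ring (per direction)
    ring_axial_positions: tuple[float, ...]  # ring centers, mm from proximal edge

    def __post_init__(self):
        if self.length <= 0:
            raise ValidationError("graft length must be positive")
        if self.proximal_diameter <= 0 or self.distal_diameter <= 0:
            raise ValidationError("graft diameters must be positive")
        if self.strut_amplitude <= 0 or self.strut_wire_width <= 0:
            raise ValidationError("strut dimensions must be positive")
        if self.strut_wire_width >= self.strut_amplitude:
            raise ValidationError("strut wire width must be smaller than the ring amplitude")
        if self.n_peaks_per_ring < 2:
            raise ValidationError("a zigzag ring needs at least 2 apices")
        pos = np.asarray(self.ring_axial_positions, dtype=float)
        if pos.size and (np.any(np.diff(pos) <= 0)):
            raise ValidationError("ring_axial_positions must be strictly increasing")
        if pos.size and (pos.min() < 0 or pos.max() > self.length):
            raise ValidationError("strut rings must lie within the graft length")
        object.__setattr__(self, "ring_axial_positions", tuple(float(p) for p in pos))

    @property
    def n_strut_rings(self) -> int:
        return len(self.ring_axial_positions)

    @property
    def tapered(self) -> bool:
        """True iff the proximal and distal diameters differ."""
        return self.proximal_diameter != self.distal_diameter

    def nominal_diameter_at(self, pgd: float | np.ndarray) -> np.ndarray:
        """Nominal fabric diameter, linearly interpolated proximal -> distal."""
        f = np.clip(np.asarray(pgd, dtype=float) / self.length, 0.0, 1.0)
        return self.proximal_diameter + f * (self.distal_diameter - self.proximal_diameter)


_ALIASES = {
    "length": ("length", "L"),
    "proximal_diameter": ("proximal_diameter", "D_prox", "d_prox"),
    "distal_diameter": ("distal_diameter", "D_dist", "d_dist"),
    "strut_amplitude": ("strut_amplitude", "amplitude"),
    "strut_wire_width": ("strut_wire_width", "wire"),
    "n_peaks_per_ring": ("n_peaks_per_ring", "peaks"),
    "ring_axial_positions": ("ring_axial_positions", "positions"),
}


def make_template(descriptor: dict) -> GraftTemplate:
    """Build a validated :class:`GraftTemplate` from a key-value descriptor.

    Accepts short aliases (``L``, ``D_prox``, ``D_dist``, ``amplitude``,
    ``wire``, ``peaks``, ``positions``, ``rings``).  A ``rings`` count, if
    given, must match ``len(positions)``.
    """
    kv = {}
    for canon, names in _ALIASES.items():
        for nm in names:
            if nm in descriptor:
                kv[canon] = descriptor[nm]
                break
        else:
            raise DescriptorError(f"graft descriptor missing required key {canon!r}")
    for key in ("length", "proximal_diameter", "distal_diameter",
                "strut_amplitude", "strut_wire_width"):
        if not (isinstance(kv[key], (int, float)) and kv[key] > 0):
            raise DescriptorError(f"descriptor value {key!r} must be a positive number")
    n_rings = descriptor.get("rings", descriptor.get("n_strut_rings"))
    if n_rings is not None and int(n_rings) != len(kv["ring_axial_positions"]):
        raise ValidationError("ring count does not match number of ring positions")
    return GraftTemplate(
        name=str(descriptor.get("name", "custom")),
        length=float(kv["length"]),
        proximal_diameter=float(kv["proximal_diameter"]),
        distal_diameter=float(kv["distal_diameter"]),
        strut_amplitude=float(kv["strut_amplitude"]),
        strut_wire_width=float(kv["strut_wire_width"]),
        n_peaks_per_ring=int(kv["n_peaks_per_ring"]),
        ring_axial_positions=tuple(kv["ring_axial_positions"]),
    )


def zigzag_segments(template: GraftTemplate, circumference, ring_index: int,
                    n_sub: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Line segments (in (AL, PGD) mm) of one strut ring, with periodic copies.

    The ring is a triangular zigzag with ``2 * n_peaks_per_ring`` legs whose
    apices alternate between ring_center +/- amplitude/2.  Apex positions are
    fixed in the *angular* coordinate theta in [0, 1); the AL of a point is
    theta times the local circumference, so on a tapered (frustum) graft the
    legs are mildly curved — pass ``n_sub`` > 1 to subdivide each leg into
    near-exact chords.  Copies at theta +/- 1 implement the AL wrap.

    ``circumference`` is either a scalar (uniform graft) or a callable
    ``C(pgd_mm)`` (tapered graft).

    Returns (seg_a, seg_b) arrays of shape (S, 2).
    """
    zc = template.ring_axial_positions[ring_index]
    half = template.strut_amplitude / 2.0
    npk = template.n_peaks_per_ring
    k = np.arange(2 * npk + 1)
    theta_ap = k / (2.0 * npk)
    z_ap = np.where(k % 2 == 0, zc - half, zc + half)
    # subdivide each leg
    t = np.linspace(0.0, 1.0, n_sub + 1)
    theta = (theta_ap[:-1, None] + t[None, :] * np.diff(theta_ap)[:, None]).ravel()
    z = (z_ap[:-1, None] + t[None, :] * np.diff(z_ap)[:, None]).ravel()
    # collapse duplicate junction points
    keep = np.ones(len(theta), dtype=bool)
    keep[n_sub + 1::n_sub + 1] = False  # first point of each subsequent leg duplicates
    theta, z = theta[keep], z[keep]
    if callable(circumference):
        C = np.asarray(circumference(z), dtype=float)
    else:
        C = float(circumference)
    seg_a, seg_b = [], []
    for shift in (-1.0, 0.0, 1.0):
        al = (theta + shift) * C
        pts = np.column_stack([al, z])
        seg_a.append(pts[:-1])
        seg_b.append(pts[1:])
    return np.vstack(seg_a), np.vstack(seg_b)


def _rasterize_struts(template: GraftTemplate, circumference, mask: Mask2D,
                      margin: float, n_sub: int) -> None:
    """Set mask pixels whose centers lie within wire/2 + margin of a strut."""
    r = template.strut_wire_width / 2.0 + margin
    res = mask.resolution
    pgd_centers = (np.arange(mask.n_rows) + 0.5) * res
    al_centers = (np.arange(mask.n_cols) + 0.5) * res
    for ri in range(template.n_strut_rings):
        zc = template.ring_axial_positions[ri]
        half = template.strut_amplitude / 2.0
        rows = np.flatnonzero(np.abs(pgd_centers - zc) <= half + r + res)
        if rows.size == 0:
            continue
        seg_a, seg_b = zigzag_segments(template, circumference, ri, n_sub=n_sub)
        AL, PGD = np.meshgrid(al_centers, pgd_centers[rows])
        pts = np.column_stack([AL.ravel(), PGD.ravel()])
        dist = dist_points_to_segments(pts, seg_a, seg_b)
        hit = (dist <= r).reshape(rows.size, mask.n_cols)
        mask.pixels[rows] |= hit


def flatten_uniform(template: GraftTemplate, resolution: float = DEFAULT_RESOLUTION,
                    *, deployed_diameter: float | None = None,
                    margin: float = DEFAULT_MARGIN) -> Mask2D:
    """Unroll a uniform-diameter graft into a rectangular graft mask.

    The cylinder is cut along the datum generator and unrolled: the mask is
    ``pi * D`` wide (one full circumference, AL-periodic) by ``length`` tall.
    ``deployed_diameter`` defaults to the nominal diameter; pass the sized
    deployed diameter so mask AL matches AL on the implanted graft.
    """
    if template.tapered:
        raise ValidationError("flatten_uniform requires a uniform-diameter template")
    if resolution <= 0:
        raise ParameterError("resolution must be positive")
    D = float(deployed_diameter if deployed_diameter is not None else template.proximal_diameter)
    circ = np.pi * D
    n_cols = int(round(circ / resolution))
    n_rows = int(round(template.length / resolution))
    mask = Mask2D(np.zeros((n_rows, n_cols), dtype=bool), resolution,
                  periodic_al=True, period_mm=circ,
                  meta={"template": template.name, "deployed_diameter": D,
                        "margin": margin})
    _rasterize_struts(template, circ, mask, margin, n_sub=1)
    return mask


def flatten_tapered(template: GraftTemplate, resolution: float = DEFAULT_RESOLUTION,
                    *, deployed_diameters: tuple[float, float] | None = None,
                    margin: float = DEFAULT_MARGIN) -> Mask2D:
    """Unroll a tapered (frustum) graft into a rectangular graft mask.

    The frustum is developed analytically: each PGD row's AL extent equals
    the local circumference ``pi * D(pgd)`` (diameter linear proximal ->
    distal); cells beyond the local circumference are not fabric and are
    marked 1 (treated as strut, i.e. forbidden).  Handles both narrowing and
    widening tapers; a zero taper defers to :func:`flatten_uniform`.
    """
    if resolution <= 0:
        raise ParameterError("resolution must be positive")
    if deployed_diameters is None:
        d_prox, d_dist = template.proximal_diameter, template.distal_diameter
    else:
        d_prox, d_dist = map(float, deployed_diameters)
    if d_prox == d_dist:
        return flatten_uniform(template, resolution, deployed_diameter=d_prox, margin=margin)

    L = template.length

    def circumference(pgd):
        f = np.clip(np.asarray(pgd, dtype=float) / L, 0.0, 1.0)
        return np.pi * (d_prox + f * (d_dist - d_prox))

    c_max = float(np.pi * max(d_prox, d_dist))
    n_cols = int(round(c_max / resolution))
    n_rows = int(round(L / resolution))
    mask = Mask2D(np.zeros((n_rows, n_cols), dtype=bool), resolution,
                  periodic_al=True, period_mm=float(np.pi * d_prox),
                  meta={"template": template.name,
                        "deployed_diameters": (d_prox, d_dist),
                        "margin": margin, "row_local_period": True})
    # invalid (non-fabric) cells beyond the row-local circumference
    pgd_centers = (np.arange(n_rows) + 0.5) * resolution
    al_centers = (np.arange(n_cols) + 0.5) * resolution
    local_c = circumference(pgd_centers)
    mask.pixels |= al_centers[None, :] > local_c[:, None]
    _rasterize_struts(template, circumference, mask, margin, n_sub=8)
    return mask


def flatten(template: GraftTemplate, resolution: float = DEFAULT_RESOLUTION, *,
            deployed_diameter=None, margin: float = DEFAULT_MARGIN) -> Mask2D:
    """Dispatch to the uniform or tapered flattening as appropriate.

    ``deployed_diameter`` may be a scalar (uniform) or (proximal, distal)
    pair (tapered).
    """
    if template.tapered:
        dd = deployed_diameter
        if dd is not None and np.isscalar(dd):
            ratio = template.distal_diameter / template.proximal_diameter
            dd = (float(dd), float(dd) * ratio)
        return flatten_tapered(template, resolution, deployed_diameters=dd, margin=margin)
    return flatten_uniform(template, resolution, deployed_diameter=deployed_diameter, margin=margin)


def load_repository(path: str | Path | None = None) -> dict[str, GraftTemplate]:
    """Load a template repository (JSON list of descriptors) by name.

    Without a path, the bundled illustrative repository is used.
    """
    if path is None:
        text = resources.files("fenplan").joinpath("data/templates.json").read_text()
    else:
        text = Path(path).read_text()
    entries = json.loads(text)
    repo = {}
    for entry in entries:
        t = make_template(entry)
        repo[t.name] = t
    return repo
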