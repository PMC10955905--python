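"""Fenestration alignment search.

The fenestration mask slides over the graft mask in the AL (rotation) and
PGD (axial translation) directions; an alignment is *valid* when no
fenestration pixel lands on a strut pixel.  The exhaustive overlap count
over all offsets is a 2D cross-correlation of the two binary masks, with
circular padding on the AL axis (rotating the graft is periodic) and
bounded support on the PGD axis (a fenestration may not cross the proximal
or distal fabric edge, which would compromise the seal).

Among valid alignments the planner picks the one minimizing the summed
per-vessel deviation delta = sqrt(dAL^2 + dPGD^2) from the measured ostium
positions.  When no rigid alignment exists, a relaxed search allows the
non-prioritized vessels (the renals) to shift independently posteriorly in
AL by up to 3 mm — the displacement experienced renal cannulators tolerate
— while the prioritized vessels (CA, SMA) stay rigid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .anatomy import FenestrationSpec, build_fenestration_mask
from .errors import InputError, NoValidFitError, ValidationError
from .geometry import wrap_difference
from .masks import Mask2D

__all__ = [
    "FitResult",
    "count_overlap",
    "overlap_map",
    "search_alignments",
    "select_optimal",
    "relaxed_search",
]

#: maximum independent posterior AL shift for non-prioritized vessels, mm
MAX_POSTERIOR_SHIFT = 3.0

#: posterior direction of an AL shift per vessel, as the sign of d(phi):
#: with phi measured clockwise-from-proximal from the anterior datum, the
#: right renal moves posterior with decreasing phi and the left renal with
#: increasing phi.
DEFAULT_POSTERIOR_SIGN = {"RRA": -1, "LRA": +1}


@dataclass
class FitResult:
    """A (possibly relaxed) graft alignment.

    ``dal``/``dpgd`` are the global rotational/axial offsets in mm relative
    to the measured (zero-deviation) placement; ``per_vessel_shift`` holds
    the independent posterior relaxations (dAL mm, dPGD mm), nonzero only
    for non-prioritized vessels when the fallback was used.
    """

    dal: float
    dpgd: float
    valid: bool
    overlap_pixels: int
    deviations: dict[str, float] = field(default_factory=dict)
    per_vessel_shift: dict[str, tuple[float, float]] = field(default_factory=dict)
    offset_px: tuple[int, int] = (0, 0)
    n_offsets_tested: int = 0
    n_valid: int = 0
    relaxed: bool = False

    @property
    def total_deviation(self) -> float:
        return float(sum(self.deviations.values()))


def _check_compatible(graft: Mask2D, fen: Mask2D) -> None:
    if abs(graft.resolution - fen.resolution) > 1e-9:
        raise InputError("graft and fenestration masks must share a resolution")


def count_overlap(graft: Mask2D, fen: Mask2D, offset: tuple[int, int]) -> int:
    """Overlap pixel count at a single offset (dal_px, dpgd_px).

    Fenestration pixel (r, c) maps to graft pixel (r + dpgd, (c + dal) mod
    n_cols).  An offset that pushes any fenestration row past the proximal
    or distal graft edge is invalid and returns a sentinel full-overlap
    count (the number of fenestration pixels, guaranteed > 0).
    """
    _check_compatible(graft, fen)
    dal, dpgd = int(offset[0]), int(offset[1])
    if dpgd < 0 or dpgd + fen.n_rows > graft.n_rows:
        return int(fen.pixels.sum())
    cols = np.mod(np.arange(fen.n_cols) + dal, graft.n_cols)
    sub = graft.pixels[dpgd:dpgd + fen.n_rows][:, cols]
    return int(np.count_nonzero(sub & fen.pixels))


def overlap_map(graft: Mask2D, fen: Mask2D) -> np.ndarray:
    """Overlap counts for every offset; shape (n_pgd_offsets, n_al_offsets).

    Row p, column a holds ``count_overlap`` at offset (a, p) for
    a in [0, graft.n_cols) (AL wraps) and p in [0, graft.n_rows -
    fen.n_rows].  Computed as an FFT cross-correlation with circular AL
    padding; counts are integers, recovered exactly by rounding.
    """
    _check_compatible(graft, fen)
    if fen.n_rows > graft.n_rows:
        return np.zeros((0, graft.n_cols), dtype=np.int64)
    g = graft.pixels.astype(np.float64)
    f = fen.pixels.astype(np.float64)
    if fen.n_cols > 1:
        g = np.concatenate([g, g[:, :fen.n_cols - 1]], axis=1)
    corr = signal.fftconvolve(g, f[::-1, ::-1], mode="valid")
    out = np.rint(corr).astype(np.int64)
    return out[:, :graft.n_cols]


def search_alignments(graft: Mask2D, fen: Mask2D, al_step: int = 1,
                      pgd_step: int = 1) -> set[tuple[int, int]]:
    """All strut-free offsets on the (periodic-AL x bounded-PGD) grid.

    Exactly equal to exhaustive nested-loop evaluation of
    :func:`count_overlap` on the same grid.
    """
    if al_step < 1 or pgd_step < 1:
        raise ValidationError("search steps must be >= 1")
    if not fen.pixels.any():
        raise InputError("fenestration mask is empty")
    m = overlap_map(graft, fen)
    rows, cols = np.nonzero(m[::pgd_step, ::al_step] == 0)
    return {(int(c * al_step), int(r * pgd_step)) for r, c in zip(rows, cols)}


def select_optimal(valid_offsets, specs: list[FenestrationSpec], fen: Mask2D,
                   graft: Mask2D, shifts_mm: dict[str, float] | None = None) -> FitResult:
    """Pick the valid offset minimizing the summed per-vessel deviation.

    delta_v = sqrt(dAL_v^2 + dPGD^2) where dAL_v includes any per-vessel
    relaxation shift.  Deterministic tie-break: smallest |dPGD|, then
    smallest |dAL|, then lexicographic offset order.
    """
    if not valid_offsets:
        raise NoValidFitError("no valid alignment among the given offsets")
    shifts_mm = shifts_mm or {}
    offs = np.asarray(sorted(valid_offsets), dtype=np.int64)
    res = graft.resolution
    period = graft.period_mm if graft.period_mm else graft.al_extent
    dal_all = wrap_difference(offs[:, 0] * res, 0.0, period)
    dpgd_all = offs[:, 1] * res - fen.origin[1]
    total = np.zeros(len(offs))
    for sp in specs:
        total += np.hypot(dal_all + shifts_mm.get(sp.vessel, 0.0), dpgd_all)
    order = np.lexsort((offs[:, 1], offs[:, 0], np.abs(dal_all),
                        np.abs(dpgd_all), total))
    i = int(order[0])
    dal_px, dpgd_px = int(offs[i, 0]), int(offs[i, 1])
    dal_mm, dpgd_mm = float(dal_all[i]), float(dpgd_all[i])
    devs = {sp.vessel: float(np.hypot(dal_mm + shifts_mm.get(sp.vessel, 0.0), dpgd_mm))
            for sp in specs}
    return FitResult(
        dal=dal_mm, dpgd=dpgd_mm, valid=True, overlap_pixels=0,
        deviations=devs,
        per_vessel_shift={v: (s, 0.0) for v, s in shifts_mm.items() if s != 0.0},
        offset_px=(dal_px, dpgd_px), n_valid=len(valid_offsets),
    )


def rigid_search(graft: Mask2D, specs: list[FenestrationSpec]) -> FitResult:
    """Plain search over global offsets only (raises NoValidFitError)."""
    fen = build_fenestration_mask(specs, graft.resolution,
                                  graft.period_mm or graft.al_extent)
    m = overlap_map(graft, fen)
    offsets = {(int(c), int(r)) for r, c in zip(*np.nonzero(m == 0))}
    if not offsets:
        raise NoValidFitError("no rigid alignment avoids the struts")
    fit = select_optimal(offsets, specs, fen, graft)
    fit.n_offsets_tested = int(m.size)
    return fit


def relaxed_search(graft: Mask2D, specs: list[FenestrationSpec],
                   max_posterior_shift: float = MAX_POSTERIOR_SHIFT, *,
                   posterior_sign: dict[str, int] | None = None) -> FitResult:
    """Alignment search with per-vessel posterior relaxation fallback.

    Global rigid offsets are preferred; if none is strut-free, the
    non-prioritized vessels may shift independently in the posterior AL
    direction by up to ``max_posterior_shift`` mm (pixel-quantized),
    prioritized vessels staying rigid.  Among feasible configurations the
    summed deviation (relaxation included) is minimized, with smaller total
    relaxation preferred on ties.  Always returns a FitResult; if even the
    relaxed search fails it carries ``valid=False`` and the smallest
    achievable overlap count as a diagnostic.
    """
    posterior_sign = dict(DEFAULT_POSTERIOR_SIGN if posterior_sign is None else posterior_sign)
    res = graft.resolution
    period = graft.period_mm or graft.al_extent
    fen = build_fenestration_mask(specs, res, period)

    # per-vessel overlap maps on the shared canvas
    per_vessel_maps = {}
    for sp in specs:
        solo = build_fenestration_mask([sp], res, period)
        # re-embed the solo disc into the full canvas rows for identical offsets
        canvas = np.zeros_like(fen.pixels)
        r0 = int(round((solo.origin[1] - fen.origin[1]) / res))
        canvas[r0:r0 + solo.n_rows] = solo.pixels
        solo_full = Mask2D(canvas, res, origin=fen.origin, period_mm=period)
        per_vessel_maps[sp.vessel] = overlap_map(graft, solo_full)

    if not per_vessel_maps:
        raise InputError("no fenestrations to place")
    shape = next(iter(per_vessel_maps.values())).shape
    if shape[0] == 0:
        return FitResult(dal=0.0, dpgd=0.0, valid=False,
                         overlap_pixels=int(fen.pixels.sum()), relaxed=True)

    movable = [sp.vessel for sp in specs if not sp.prioritized]
    fixed_total = sum(per_vessel_maps[sp.vessel] for sp in specs if sp.prioritized)
    if np.isscalar(fixed_total):
        fixed_total = np.zeros(shape, dtype=np.int64)

    max_px = int(np.floor(max_posterior_shift / res + 1e-9))
    steps = range(max_px + 1)
    W = shape[1]

    best = None            # (key, offset, shifts_mm)
    min_overlap = None
    combos = sorted(itertools.product(*[steps] * len(movable)), key=lambda c: sum(c))
    n_tested = 0
    for combo in combos:
        total = fixed_total.copy()
        for v, s_px in zip(movable, combo):
            sgn = posterior_sign.get(v, -1)
            total += np.roll(per_vessel_maps[v], -sgn * s_px, axis=1)
        n_tested += total.size
        cur_min = int(total.min())
        if min_overlap is None or cur_min < min_overlap:
            min_overlap = cur_min
        rows, cols = np.nonzero(total == 0)
        if rows.size == 0:
            continue
        shifts_mm = {v: posterior_sign.get(v, -1) * s_px * res
                     for v, s_px in zip(movable, combo) if s_px}
        offsets = {(int(c), int(r)) for r, c in zip(rows, cols)}
        cand = select_optimal(offsets, specs, fen, graft, shifts_mm=shifts_mm)
        key = (cand.total_deviation, sum(combo), abs(cand.dpgd), abs(cand.dal))
        if best is None or key < best[0]:
            best = (key, cand)
    if best is None:
        return FitResult(dal=0.0, dpgd=0.0, valid=False,
                         overlap_pixels=int(min_overlap), relaxed=True,
                         n_offsets_tested=n_tested)
    fit = best[1]
    fit.relaxed = any(s != (0.0, 0.0) for s in fit.per_vessel_shift.values())
    fit.n_offsets_tested = n_tested
    return fit


def plan_alignment(graft: Mask2D, specs: list[FenestrationSpec],
                   max_posterior_shift: float = MAX_POSTERIOR_SHIFT, *,
                   posterior_sign: dict[str, int] | None = None) -> FitResult:
    """Rigid search with automatic relaxation fallback."""
    try:
        return rigid_search(graft, specs)
    except NoValidFitError:
        return relaxed_search(graft, specs, max_posterior_shift,
                              posterior_sign=posterior_sign)
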