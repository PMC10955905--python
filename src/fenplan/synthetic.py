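"""Synthetic aortas with known ground truth, for testing every stage.

Cases emulate the CT-derived planning inputs: a tubular lumen labelmap
swept along a parametric centerline (straight, planar arc, or tortuous
3D curve), plus visceral ostium points (CA, SMA, RRA, LRA) placed on the
lumen wall at known angles and axial stations.  The generator records the
exact (phi, station) of every ostium — recomputed analytically after any
measurement noise is applied to the 3D point — so parameter-recovery error
of the measurement/search/mapping pipeline can be quantified without any
clinical data.

Synthetic conventions (package choices, not clinical facts): a 24 mm
uniform visceral aorta; anterior datum +y; celiac and SMA anterior
(phi ~ 355 and 10 deg) and prioritized; renals lateral/posterior
(phi ~ 265 and 95 deg), 6 mm, non-prioritized; PGD stations 21/30/54/57 mm
below the graft top, chosen to fall within the fabric windows of the
bundled 26 mm device at realistic ring pitch, with per-case jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError, ValidationError
from .geometry import circumferential_direction, project_out, unit
from .masks import Mask2D

__all__ = ["SyntheticCase", "generate_case", "generate_adversarial", "AdversarialCase"]

DEFAULT_SPACING = 0.7          # mm, isotropic (CT-angiography scale)
DEFAULT_RADIUS = 12.0          # mm lumen radius (24 mm visceral aorta)
DEFAULT_LENGTH = 200.0         # mm of centerline
DEFAULT_TOP_STATION = 40.0     # graft top, mm of centerline arclength
                               # (kept well clear of the segmentation cut ends,
                               # as a planner would choose a landing zone)
DATUM = np.array([0.0, 1.0, 0.0])  # anterior

# vessel -> (phi deg, PGD mm below graft top, diameter mm, prioritized)
VESSEL_LAYOUT = {
    "CA": (355.0, 21.0, 7.0, True),
    "SMA": (10.0, 30.0, 7.0, True),
    "RRA": (265.0, 54.0, 6.0, False),
    "LRA": (95.0, 57.0, 6.0, False),
}
PHI_JITTER = 8.0               # deg, uniform half-range
PGD_JITTER = 1.2               # mm, uniform half-range


class _AnalyticCurve:
    """Dense-polyline representation of an analytic centerline."""

    def __init__(self, fn, u_max: float, n: int = 8000):
        u = np.linspace(0.0, u_max, n)
        self.points = np.asarray(fn(u), dtype=float)
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(self.arclength[-1])
        d = np.gradient(self.points, self.arclength, axis=0)
        self.tangents = unit(d)

    def point(self, s):
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        out = np.empty(np.shape(s) + (3,))
        for k in range(3):
            out[..., k] = np.interp(s, self.arclength, self.points[:, k])
        return out

    def tangent(self, s):
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        out = np.empty(np.shape(s) + (3,))
        for k in range(3):
            out[..., k] = np.interp(s, self.arclength, self.tangents[:, k])
        return unit(out)

    def project(self, p):
        d2 = np.sum((self.points - np.asarray(p, dtype=float)) ** 2, axis=1)
        i = int(np.argmin(d2))
        if 0 < i < len(d2) - 1:
            denom = d2[i - 1] - 2 * d2[i] + d2[i + 1]
            if abs(denom) > 1e-12:
                t = float(np.clip(0.5 * (d2[i - 1] - d2[i + 1]) / denom, -1.0, 1.0))
                step = self.arclength[i + 1] - self.arclength[i] if t >= 0 \
                    else self.arclength[i] - self.arclength[i - 1]
                return float(self.arclength[i] + t * step)
        return float(self.arclength[i])


def _profile_curve(profile: str) -> _AnalyticCurve:
    if profile == "straight":
        return _AnalyticCurve(
            lambda u: np.column_stack([np.zeros_like(u), np.zeros_like(u), -u]),
            DEFAULT_LENGTH)
    if profile == "arc":
        R = 150.0
        return _AnalyticCurve(
            lambda u: np.column_stack([R * (1.0 - np.cos(u / R)),
                                       np.zeros_like(u),
                                       -R * np.sin(u / R)]),
            DEFAULT_LENGTH)
    if profile == "tortuous":
        a1, l1, a2, l2 = 6.0, 100.0, 6.0, 70.0
        return _AnalyticCurve(
            lambda u: np.column_stack([a1 * np.sin(2 * np.pi * u / l1),
                                       a2 * np.sin(2 * np.pi * u / l2 + 1.0),
                                       -u]),
            DEFAULT_LENGTH)
    raise InputError(f"unsupported profile {profile!r}")


@dataclass
class SyntheticCase:
    """A synthetic aorta with complete ground truth."""

    profile: str
    seed: int
    noise_sd: float
    curve: _AnalyticCurve
    lumen_radius: float
    ostia: list[dict]                 # vessel, point, diameter, prioritized,
                                      # phi_truth, station_truth, pgd_truth
    labelmap: np.ndarray
    spacing: np.ndarray
    graft_top_station: float = DEFAULT_TOP_STATION
    datum: np.ndarray = field(default_factory=lambda: DATUM.copy())
    template_name: str = "thoracic-straight-26"

    @property
    def graft_top_point(self) -> np.ndarray:
        """3D point of the graft top on the true centerline (image landmark)."""
        return self.curve.point(self.graft_top_station)

    def truth_uv(self, deployed_diameter: float) -> dict[str, tuple[float, float]]:
        """Ground-truth (AL, PGD) per vessel at the given deployed diameter."""
        return {o["vessel"]: (o["phi_truth"] / 360.0 * np.pi * deployed_diameter,
                              o["pgd_truth"]) for o in self.ostia}

    def write_files(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the NIfTI labelmap and ostia CSV the anatomy module consumes."""
        import nibabel as nib
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*self.spacing, 1.0])
        nii = outdir / "lumen.nii"
        nib.save(nib.Nifti1Image(self.labelmap.astype(np.uint8), affine), str(nii))
        csv = outdir / "ostia.csv"
        pd.DataFrame([
            {"vessel": o["vessel"], "x": o["point"][0], "y": o["point"][1],
             "z": o["point"][2], "diameter": o["diameter"],
             "prioritized": o["prioritized"]}
            for o in self.ostia
        ]).to_csv(csv, index=False)
        return {"labelmap": nii, "ostia": csv}


def _rasterize_tube(curve: _AnalyticCurve, radius: float,
                    spacing: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary tube labelmap by stamping balls along the curve.

    Returns (volume, spacing_vec, world_offset): world coordinates satisfy
    world = voxel_center = (index + 0.5) * spacing, with the curve shifted
    by ``world_offset`` so everything is inside the volume.
    """
    pad = radius + 3.0 * spacing
    lo = curve.points.min(axis=0) - pad
    hi = curve.points.max(axis=0) + pad
    offset = -lo
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    vol = np.zeros(shape, dtype=bool)

    n_samp = max(2, int(np.ceil(curve.length / (0.5 * spacing))))
    samples = curve.point(np.linspace(0.0, curve.length, n_samp)) + offset

    r_vox = int(np.floor(radius / spacing)) + 1
    g = np.arange(-r_vox, r_vox + 1)
    OX, OY, OZ = np.meshgrid(g, g, g, indexing="ij")
    ball = np.column_stack([OX.ravel(), OY.ravel(), OZ.ravel()])
    ball = ball[np.linalg.norm(ball * spacing, axis=1) <= radius]

    centers = np.rint(samples / spacing - 0.5).astype(int)
    for lo_i in range(0, len(centers), 16):
        idx = (centers[lo_i:lo_i + 16, None, :] + ball[None, :, :]).reshape(-1, 3)
        np.clip(idx, 0, np.array(shape) - 1, out=idx)
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    # flat axial cuts at the curve ends, like a real segmentation cropped to
    # the scanned field of view (no rounded end caps)
    z_centers = (np.arange(shape[2]) + 0.5) * spacing
    z_hi = samples[0, 2]    # proximal (largest z)
    z_lo = samples[-1, 2]   # distal
    vol[:, :, (z_centers > z_hi) | (z_centers < z_lo)] = False
    return vol, np.full(3, float(spacing)), offset


def generate_case(profile: str = "straight", noise_sd: float = 0.0,
                  seed: int = 0, *, spacing: float = DEFAULT_SPACING,
                  lumen_radius: float = DEFAULT_RADIUS,
                  layout: dict | None = None, jitter: bool = True) -> SyntheticCase:
    """Generate a deterministic synthetic planning case.

    ``noise_sd`` (mm) is isotropic Gaussian measurement noise applied to
    each ostium point; the stored ground truth is the analytic (phi,
    station) of the *noisy* point, so recovery errors isolate pipeline
    error from the injected noise.
    """
    rng = np.random.default_rng(seed)
    curve = _profile_curve(profile)
    layout = dict(VESSEL_LAYOUT if layout is None else layout)

    vol, sp, offset = _rasterize_tube(curve, lumen_radius, spacing)
    # shift the curve into the volume's world frame once and for all
    shifted = _AnalyticCurve.__new__(_AnalyticCurve)
    shifted.points = curve.points + offset
    shifted.arclength = curve.arclength
    shifted.length = curve.length
    shifted.tangents = curve.tangents
    curve = shifted

    ostia = []
    for vessel, (phi0, pgd0, diam, prio) in layout.items():
        phi = phi0 + (rng.uniform(-PHI_JITTER, PHI_JITTER) if jitter else 0.0)
        pgd = pgd0 + (rng.uniform(-PGD_JITTER, PGD_JITTER) if jitter else 0.0)
        station = DEFAULT_TOP_STATION + pgd
        c = curve.point(station)
        t = curve.tangent(station)
        dp = unit(project_out(DATUM, t))
        point = c + lumen_radius * circumferential_direction(t, dp, phi)
        point = point + rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else point
        # analytic truth of the (possibly noisy) point
        s_true = curve.project(point)
        t_true = curve.tangent(s_true)
        dp_true = unit(project_out(DATUM, t_true))
        d = unit(project_out(point - curve.point(s_true), t_true))
        from .geometry import signed_angle_about
        phi_true = signed_angle_about(t_true, dp_true, d)
        ostia.append({
            "vessel": vessel, "point": point, "diameter": diam,
            "prioritized": prio, "phi_truth": float(phi_true),
            "station_truth": float(s_true),
            "pgd_truth": float(s_true - DEFAULT_TOP_STATION),
        })

    return SyntheticCase(profile=profile, seed=seed, noise_sd=noise_sd,
                         curve=curve, lumen_radius=lumen_radius, ostia=ostia,
                         labelmap=vol, spacing=sp)


# -- adversarial constructions -------------------------------------------

@dataclass
class AdversarialCase:
    """A mask-level construction guaranteeing a named search outcome."""

    kind: str
    graft_mask: Mask2D
    specs: list
    expected: str
    shift_vessel: str | None = None
    shift_mm: float = 0.0
    case: SyntheticCase | None = None


def generate_adversarial(kind: str, seed: int = 0, *,
                         resolution: float = 0.25) -> AdversarialCase:
    """Construct a case with a guaranteed search outcome.

    ``blocked_renal``: every rigid offset overlaps a strut, but shifting the
    left renal posteriorly by 2 mm yields a strut-free fit (verified
    internally by brute force at construction time).
    ``no_fit``: the graft mask is fully covered; even the relaxed search
    must report valid=False.
    ``edge_fenestration``: an ostium beyond the graft's axial coverage; the
    measurement stage must raise the out-of-coverage error.
    """
    from .anatomy import FenestrationSpec, build_fenestration_mask
    from .search import (DEFAULT_POSTERIOR_SIGN, relaxed_search, rigid_search)
    from .errors import NoValidFitError

    rng = np.random.default_rng(seed)
    period = np.pi * 24.0
    specs = [
        FenestrationSpec("CA", 355.0, 355.0 / 360 * period, 21.0, 7.0, True),
        FenestrationSpec("SMA", 10.0, 10.0 / 360 * period, 30.0, 7.0, True),
        FenestrationSpec("RRA", 265.0, 265.0 / 360 * period, 54.0, 6.0, False),
        FenestrationSpec("LRA", 95.0, 95.0 / 360 * period, 57.0, 6.0, False),
    ]

    if kind == "edge_fenestration":
        case = generate_case("straight", 0.0, seed)
        # an ostium 10 mm beyond the distal fabric edge of a 116 mm graft
        station = DEFAULT_TOP_STATION + 126.0
        c = case.curve.point(station)
        t = case.curve.tangent(station)
        dp = unit(project_out(DATUM, t))
        pt = c + case.lumen_radius * circumferential_direction(t, dp, 180.0)
        case.ostia.append({"vessel": "AccRA", "point": pt, "diameter": 5.0,
                           "prioritized": False, "phi_truth": 180.0,
                           "station_truth": station, "pgd_truth": 126.0})
        g = Mask2D(np.zeros((int(116 / resolution), int(round(period / resolution))), bool),
                   resolution, periodic_al=True, period_mm=period)
        return AdversarialCase(kind, g, specs, "out_of_coverage", case=case)

    n_rows = int(round(116.0 / resolution))
    n_cols = int(round(period / resolution))

    if kind == "no_fit":
        g = Mask2D(np.ones((n_rows, n_cols), dtype=bool), resolution,
                   periodic_al=True, period_mm=period)
        fit = relaxed_search(g, specs)
        assert not fit.valid
        return AdversarialCase(kind, g, specs, "invalid")

    if kind == "blocked_renal":
        shift_mm = 2.0
        vessel = "LRA"
        sgn = DEFAULT_POSTERIOR_SIGN[vessel]
        pixels = np.ones((n_rows, n_cols), dtype=bool)
        al_c = (np.arange(n_cols) + 0.5) * resolution
        pgd_c = (np.arange(n_rows) + 0.5) * resolution

        def carve(al, pgd, radius):
            from .geometry import wrap_difference
            dal = wrap_difference(al_c, al % period, period)
            d2 = dal[None, :] ** 2 + (pgd_c[:, None] - pgd) ** 2
            pixels[d2 <= radius * radius] = False

        for sp in specs:
            target_al = sp.al + (sgn * shift_mm if sp.vessel == vessel else 0.0)
            carve(target_al, sp.pgd, sp.diameter / 2.0 + 2.5 * resolution)
        g = Mask2D(pixels, resolution, periodic_al=True, period_mm=period)
        # verify the guaranteed outcome by brute force
        try:
            rigid_search(g, specs)
            raise ValidationError("adversarial construction failed: rigid fit exists")
        except NoValidFitError:
            pass
        fit = relaxed_search(g, specs)
        assert fit.valid and vessel in fit.per_vessel_shift
        return AdversarialCase(kind, g, specs, "relaxed_valid",
                               shift_vessel=vessel, shift_mm=sgn * shift_mm)

    raise InputError(f"unsupported adversarial kind {kind!r}")
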