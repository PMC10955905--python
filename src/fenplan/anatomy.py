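"""Aortic centerline extraction and fenestration measurement.

The planning inputs are an aortic lumen segmentation (binary labelmap) and
the 3D ostium centers of the target visceral vessels (celiac, SMA, renals).
This module reduces them to the two surface coordinates the search works
in: the circumferential arclength AL and the proximal graft distance PGD,
and rasterizes the target vessels into the *fenestration mask* — a rigid
constellation of discs, one per vessel, at their measured (AL, PGD)
positions.

Coordinate conventions (see :mod:`fenplan.geometry`): centerlines run
proximal to distal, phi is measured clockwise from the projected datum
vector as seen from proximal, and AL = (phi/360) * pi * deployed diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InputError, OutOfCoverageError, ValidationError
from .geometry import (project_out, rotation_minimizing_normals,
                       signed_angle_about, unit, wrap_difference)
from .masks import Mask2D
from .meshing import fit_centerline_spline

__all__ = [
    "Centerline",
    "FenestrationSpec",
    "compute_centerline",
    "centerline_from_polyline",
    "measure_fenestration",
    "build_fenestration_mask",
    "load_labelmap",
    "load_ostia",
]

VESSEL_LABELS = ("CA", "SMA", "RRA", "LRA")


@dataclass
class Centerline:
    """Sampled aortic centerline with per-station lumen diameter and frames.

    ``points`` are ordered proximal to distal; ``arclength`` is cumulative
    mm from the proximal end; ``normals``/``binormals`` complete a
    rotation-minimizing orthonormal triad with the tangent.
    """

    points: np.ndarray          # (N, 3)
    arclength: np.ndarray       # (N,)
    local_diameter: np.ndarray  # (N,)
    tangents: np.ndarray        # (N, 3)
    normals: np.ndarray         # (N, 3)
    binormals: np.ndarray       # (N, 3)
    spline: object = None       # CenterlineSpline used to build the stations

    def __post_init__(self):
        if len(self.points) < 4:
            raise InputError("centerline needs at least 4 stations")
        if np.any(np.diff(self.arclength) <= 0):
            raise InputError("centerline arclength must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def point_at(self, s):
        if self.spline is not None:
            return self.spline.point(s)
        return self._interp(self.points, s)

    def tangent_at(self, s):
        if self.spline is not None:
            return self.spline.tangent(s)
        return unit(self._interp(self.tangents, s))

    def diameter_at(self, s):
        return np.interp(np.asarray(s, dtype=float), self.arclength, self.local_diameter)

    def _interp(self, arr, s):
        s = np.asarray(s, dtype=float)
        out = np.empty(s.shape + (3,))
        for k in range(3):
            out[..., k] = np.interp(s, self.arclength, arr[:, k])
        return out

    def project(self, p: np.ndarray) -> float:
        """Arclength of the foot point of ``p`` on the centerline.

        Nearest dense station followed by one parabolic refinement of the
        squared distance, accurate to well under the station spacing.
        """
        p = np.asarray(p, dtype=float)
        d2 = np.sum((self.points - p) ** 2, axis=1)
        i = int(np.argmin(d2))
        if 0 < i < len(d2) - 1:
            denom = d2[i - 1] - 2 * d2[i] + d2[i + 1]
            if abs(denom) > 1e-12:
                t = 0.5 * (d2[i - 1] - d2[i + 1]) / denom
                t = float(np.clip(t, -1.0, 1.0))
                if t >= 0:
                    lo, hi = self.arclength[i], self.arclength[min(i + 1, len(d2) - 1)]
                    return float(self.arclength[i] + t * (hi - self.arclength[i]))
                lo = self.arclength[max(i - 1, 0)]
                return float(self.arclength[i] + t * (self.arclength[i] - lo))
        return float(self.arclength[i])


@dataclass
class FenestrationSpec:
    """One target vessel expressed in graft-surface coordinates."""

    vessel: str
    phi: float          # degrees from datum, clockwise from proximal view
    al: float           # mm around the deployed graft
    pgd: float          # mm from the proximal graft edge
    diameter: float     # fenestration (vessel) diameter, mm
    prioritized: bool = False

    def __post_init__(self):
        self.phi = float(np.mod(self.phi, 360.0))
        if self.pgd < 0:
            raise ValidationError(f"vessel {self.vessel}: PGD must be >= 0")
        if self.diameter <= 0:
            raise ValidationError(f"vessel {self.vessel}: diameter must be positive")


def compute_centerline(labelmap: np.ndarray, spacing, *, proximal: str = "high",
                       smoothing: float | None = None,
                       station_spacing: float = 0.5) -> Centerline:
    """Centerline from a binary lumen labelmap.

    Per axial (z) voxel slice, the lumen centroid and equivalent-area circle
    diameter are computed; the centroids are smoothed with a spline of best
    fit and resampled at ``station_spacing`` mm.  The equivalent diameter is
    corrected for tube obliquity (an oblique cut of a circular tube is an
    ellipse whose area overestimates the lumen by 1/cos theta).

    ``proximal`` selects which end of the z axis is proximal ('high' =
    larger z index, the usual superior end).  A disconnected lumen triggers
    a warning and the largest connected component is used.
    """
    labelmap = np.asarray(labelmap)
    if labelmap.ndim != 3:
        raise InputError("labelmap must be a 3D volume")
    labelmap = labelmap > 0
    if not labelmap.any():
        raise InputError("labelmap is empty")
    spacing = np.asarray(spacing, dtype=float)
    lab, n = ndimage.label(labelmap)
    if n > 1:
        warnings.warn(f"lumen labelmap has {n} connected components; using largest")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        labelmap = lab == (1 + int(np.argmax(sizes)))

    zs = np.flatnonzero(labelmap.any(axis=(0, 1)))
    if len(zs) < 4:
        raise InputError("lumen must span at least 4 axial slices")
    centroids, areas = [], []
    for z in zs:
        sl = labelmap[:, :, z]
        cy, cx = ndimage.center_of_mass(sl)
        centroids.append(((cy + 0.5) * spacing[0], (cx + 0.5) * spacing[1],
                          (z + 0.5) * spacing[2]))
        areas.append(sl.sum() * spacing[0] * spacing[1])
    centroids = np.asarray(centroids)
    areas = np.asarray(areas, dtype=float)
    if proximal == "high":
        centroids, areas = centroids[::-1], areas[::-1]

    spline = fit_centerline_spline(centroids, smoothing=smoothing)
    n_st = max(4, int(np.ceil(spline.length / station_spacing)) + 1)
    s = np.linspace(0.0, spline.length, n_st)
    pts = spline.point(s)
    tans = spline.tangent(s)

    # equivalent diameter per slice, obliquity-corrected, mapped to arclength
    d_eq = 2.0 * np.sqrt(areas / np.pi)
    slice_arc = np.empty(len(centroids))
    for i, c in enumerate(centroids):
        slice_arc[i] = s[np.argmin(np.sum((pts - c) ** 2, axis=1))]
    obliq = np.abs(np.interp(slice_arc, s, np.abs(tans[:, 2])))
    obliq = np.clip(obliq, 0.2, 1.0)
    d_corr = d_eq * np.sqrt(obliq)
    order = np.argsort(slice_arc)
    diam = np.interp(s, slice_arc[order], d_corr[order])

    normals = rotation_minimizing_normals(pts, tans)
    binormals = np.cross(tans, normals)
    return Centerline(points=pts, arclength=s, local_diameter=diam,
                      tangents=tans, normals=normals, binormals=binormals,
                      spline=spline)


def centerline_from_polyline(points, diameters, *, smoothing: float | None = None,
                             station_spacing: float = 0.5) -> Centerline:
    """Centerline directly from an ordered polyline with per-point diameters.

    Alternative input path when a centerline has already been extracted by
    other software; bypasses the labelmap stage entirely.
    """
    points = np.asarray(points, dtype=float)
    diameters = np.broadcast_to(np.asarray(diameters, dtype=float), (len(points),))
    spline = fit_centerline_spline(points, smoothing=smoothing)
    n_st = max(4, int(np.ceil(spline.length / station_spacing)) + 1)
    s = np.linspace(0.0, spline.length, n_st)
    pts = spline.point(s)
    tans = spline.tangent(s)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    chord = chord * (spline.length / chord[-1])
    diam = np.interp(s, chord, diameters)
    normals = rotation_minimizing_normals(pts, tans)
    return Centerline(points=pts, arclength=s, local_diameter=diam,
                      tangents=tans, normals=normals,
                      binormals=np.cross(tans, normals), spline=spline)


def measure_fenestration(centerline: Centerline, ostium, datum,
                         deployed_diameter: float, graft_top_station: float,
                         *, vessel: str = "other", diameter: float = 6.0,
                         prioritized: bool = False,
                         graft_length: float | None = None) -> FenestrationSpec:
    """Measure a vessel ostium's (phi, AL, PGD) on the deployed graft.

    PGD is the centerline arclength from the graft top to the ostium's foot
    point; phi is the clockwise angle (from proximal) between the projected
    datum and the ostium direction in the cross-sectional plane; AL converts
    phi to surface millimetres at the deployed diameter.
    """
    ostium = np.asarray(ostium, dtype=float)
    s = centerline.project(ostium)
    pgd = s - graft_top_station
    if pgd < 0 or (graft_length is not None and pgd > graft_length):
        raise OutOfCoverageError(vessel)
    foot = np.atleast_2d(centerline.point_at(s))[0]
    t = np.atleast_2d(centerline.tangent_at(s))[0]
    dp = project_out(np.asarray(datum, dtype=float), t)
    if np.linalg.norm(dp) < 1e-6:
        raise InputError("datum vector is parallel to the local tangent")
    dp = dp / np.linalg.norm(dp)
    d = project_out(ostium - foot, t)
    if np.linalg.norm(d) < 1e-9:
        raise InputError(f"vessel {vessel}: ostium lies on the centerline")
    d = d / np.linalg.norm(d)
    phi = signed_angle_about(t, dp, d)
    al = phi / 360.0 * np.pi * deployed_diameter
    return FenestrationSpec(vessel=vessel, phi=phi, al=al, pgd=float(pgd),
                            diameter=diameter, prioritized=prioritized)


def build_fenestration_mask(specs: list[FenestrationSpec], resolution: float,
                            al_period: float) -> Mask2D:
    """Rasterize the vessel constellation into the fenestration mask.

    Each fenestration is a filled disc of the vessel diameter centered at
    (AL mod period, PGD).  The canvas spans one full AL period (so a disc
    near the seam wraps correctly) and is tight in PGD; ``origin`` records
    the PGD of row 0 so the search can convert offsets back to mm.  Disc
    rasterization uses the exact real-valued centers, so the relative
    distances of the rigid constellation are preserved exactly.
    """
    if not specs:
        raise InputError("need at least one fenestration")
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    radii = np.array([sp.diameter / 2.0 for sp in specs])
    al = np.array([np.mod(sp.al, al_period) for sp in specs])
    pgd = np.array([sp.pgd for sp in specs])
    # overlapping discs are anatomically impossible (vessels would merge)
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            dal = wrap_difference(al[i], al[j], al_period)
            dist = float(np.hypot(dal, pgd[i] - pgd[j]))
            if dist < radii[i] + radii[j]:
                raise ValidationError(
                    f"fenestrations {specs[i].vessel} and {specs[j].vessel} overlap")

    n_cols = int(round(al_period / resolution))
    pgd0 = np.floor((pgd - radii).min() / resolution) * resolution
    pgd1 = np.ceil((pgd + radii).max() / resolution) * resolution
    n_rows = int(round((pgd1 - pgd0) / resolution))
    mask = Mask2D(np.zeros((n_rows, n_cols), dtype=bool), resolution,
                  periodic_al=False, period_mm=al_period, origin=(0.0, pgd0),
                  centers_px={})
    al_c = (np.arange(n_cols) + 0.5) * resolution
    pgd_c = pgd0 + (np.arange(n_rows) + 0.5) * resolution
    for sp, a, p, r in zip(specs, al, pgd, radii):
        dal = wrap_difference(al_c, a, al_period)
        d2 = dal[None, :] ** 2 + (pgd_c[:, None] - p) ** 2
        mask.pixels |= d2 <= r * r
        mask.centers_px[sp.vessel] = (a / resolution - 0.5, (p - pgd0) / resolution - 0.5)
    return mask


# -- file I/O -------------------------------------------------------------

def load_labelmap(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI labelmap; returns (binary volume, voxel spacing mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > 0
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, spacing


def load_ostia(path: str | Path) -> list[dict]:
    """Read an ostia table (CSV or JSON): vessel, x, y, z, diameter, prioritized."""
    import pandas as pd

    path = Path(path)
    if path.suffix.lower() == ".json":
        import json
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    out = []
    for r in rows:
        out.append({
            "vessel": str(r["vessel"]),
            "point": np.array([float(r["x"]), float(r["y"]), float(r["z"])]),
            "diameter": float(r.get("diameter", 6.0)),
            "prioritized": bool(r.get("prioritized", r.get("vessel") in ("CA", "SMA"))),
        })
    if not out:
        raise InputError(f"no ostia found in {path}")
    return out
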