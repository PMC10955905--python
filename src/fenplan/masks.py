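"""2D binary masks in (AL, PGD) graft-surface coordinates.

A :class:`Mask2D` is the discretized search space used by the alignment
search: columns run along the arclength (AL, circumferential) axis, rows
along the proximal-graft-distance (PGD, axial) axis.  Row 0 is the proximal
graft edge; column 0 is the datum (phi = 0) generator.  Pixel (i, j) covers
the half-open cell [origin + j*res, origin + (j+1)*res) x [...] and its
center sits at origin + (j + 0.5) * res.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = ["Mask2D"]


@dataclass
class Mask2D:
    """Binary image over the developed (unrolled) graft surface.

    Parameters
    ----------
    pixels
        Boolean array, shape (n_rows, n_cols); rows = PGD, cols = AL.
    resolution
        Pixel edge length in mm (isotropic).
    periodic_al
        True for graft masks, whose AL axis wraps (the graft is a closed
        tube).  Fenestration masks are not periodic themselves; periodicity
        is applied by the search.
    period_mm
        Exact AL period (circumference) in mm.  ``al_extent`` is the pixel
        extent ``n_cols * resolution`` which may differ from the true
        circumference by up to one pixel due to column rounding; AL <->
        column conversions should use ``period_mm`` where exactness matters.
    origin
        (AL, PGD) in mm of the corner of pixel (0, 0); (0, 0) for graft
        masks, possibly a positive PGD for tight fenestration canvases.
    centers_px
        Optional map vessel -> (col, row) float pixel-center coordinates of
        rasterized fenestration centers (fenestration masks only).
    """

    pixels: np.ndarray
    resolution: float
    periodic_al: bool = False
    period_mm: float | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    centers_px: dict[str, tuple[float, float]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError("mask pixels must be a 2D array")
        if self.pixels.dtype != bool:
            vals = np.unique(self.pixels)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError("mask pixels must be strictly binary")
            self.pixels = self.pixels.astype(bool)
        if self.resolution <= 0:
            raise ParameterError("resolution must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def al_extent(self) -> float:
        """AL pixel extent in mm (= n_cols * resolution)."""
        return self.n_cols * self.resolution

    @property
    def pgd_extent(self) -> float:
        """PGD pixel extent in mm (= n_rows * resolution)."""
        return self.n_rows * self.resolution

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(AL, PGD) mm coordinates of all pixel centers, each (n_rows, n_cols)."""
        al0, pgd0 = self.origin
        al = al0 + (np.arange(self.n_cols) + 0.5) * self.resolution
        pgd = pgd0 + (np.arange(self.n_rows) + 0.5) * self.resolution
        return np.meshgrid(al, pgd)

    # -- I/O --------------------------------------------------------------
    def to_png(self, path: str | Path) -> Path:
        """Write the mask as a binary PNG plus a JSON sidecar with geometry."""
        from PIL import Image

        path = Path(path)
        Image.fromarray((self.pixels.astype(np.uint8)) * 255).save(path)
        sidecar = {
            "resolution_mm_per_px": self.resolution,
            "al_extent_mm": self.al_extent,
            "pgd_extent_mm": self.pgd_extent,
            "periodic_al": self.periodic_al,
            "period_mm": self.period_mm,
            "origin_mm": list(self.origin),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
        return path
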