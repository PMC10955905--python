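"""Brute-force oracles shared by the search tests and the acceptance suite.

These deliberately avoid the FFT/correlation code paths of the package: the
overlap oracle accumulates shifted graft windows pixel by pixel over the
fenestration support.
"""

import numpy as np

from fenplan.masks import Mask2D


def brute_overlap_map(graft: np.ndarray, fen: np.ndarray) -> np.ndarray:
    """Overlap count per (dPGD, dAL) offset by direct summation."""
    Hg, W = graft.shape
    Hf, Wf = fen.shape
    if Hf > Hg:
        return np.zeros((0, W), dtype=int)
    g2 = np.concatenate([graft, graft[:, :Wf]], axis=1).astype(int)
    out = np.zeros((Hg - Hf + 1, W), dtype=int)
    for r, c in zip(*np.nonzero(fen)):
        for p in range(Hg - Hf + 1):
            row = g2[p + r]
            out[p] += np.concatenate([row[c:c + W], row[:0]]) if c + W <= len(row) \
                else np.concatenate([row[c:], row[:c + W - len(row)]])
    return out


def random_masks(seed, shape=(64, 64), fen_shape=(16, 16), density=0.2):
    """A random strut mask and a random sparse fenestration mask."""
    rng = np.random.default_rng(seed)
    g = Mask2D(rng.random(shape) < density, 1.0, periodic_al=True,
               period_mm=float(shape[1]))
    f = Mask2D(rng.random(fen_shape) < 0.1, 1.0, origin=(0.0, 0.0))
    if not f.pixels.any():
        f.pixels[fen_shape[0] // 2, fen_shape[1] // 2] = True
    return g, f
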