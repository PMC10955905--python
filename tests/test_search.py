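"""Alignment search, checked against brute-force oracles.

The brute-force overlap oracle accumulates, for every fenestration pixel,
the graft window it can land on — an O(F x offsets) summation completely
independent of the FFT correlation used by the implementation.
"""

import numpy as np
import pytest

import fenplan as fp
from fenplan import search
from fenplan.anatomy import FenestrationSpec, build_fenestration_mask
from fenplan.errors import InputError, NoValidFitError
from fenplan.masks import Mask2D


from oracles import brute_overlap_map, random_masks  # noqa: E402


class TestCountOverlap:
    def test_zero_graft_no_overlap(self):
        g = Mask2D(np.zeros((20, 30), bool), 1.0, periodic_al=True)
        f = Mask2D(np.ones((5, 5), bool), 1.0)
        assert fp.count_overlap(g, f, (7, 3)) == 0

    def test_matches_nested_loop_on_disc_and_strut(self):
        g = np.zeros((40, 40), bool)
        g[18:22] = True                         # strut band
        f = np.zeros((11, 11), bool)
        yy, xx = np.mgrid[:11, :11]
        f[(yy - 5) ** 2 + (xx - 5) ** 2 <= 25] = True
        gm = Mask2D(g, 1.0, periodic_al=True)
        fm = Mask2D(f, 1.0)
        for dal, dpgd in [(0, 14), (3, 10), (20, 16), (35, 5)]:
            expected = 0
            for r in range(11):
                for c in range(11):
                    if f[r, c] and g[r + dpgd, (c + dal) % 40]:
                        expected += 1
            assert fp.count_overlap(gm, fm, (dal, dpgd)) == expected

    def test_beyond_distal_edge_is_sentinel_invalid(self):
        g = Mask2D(np.zeros((20, 30), bool), 1.0, periodic_al=True)
        f = Mask2D(np.ones((5, 5), bool), 1.0)
        assert fp.count_overlap(g, f, (0, 16)) == 25
        assert fp.count_overlap(g, f, (0, -1)) == 25

    def test_resolution_mismatch_rejected(self):
        g = Mask2D(np.zeros((20, 30), bool), 1.0)
        f = Mask2D(np.ones((5, 5), bool), 0.5)
        with pytest.raises(InputError):
            fp.count_overlap(g, f, (0, 0))


class TestSearchAlignments:
    def test_zero_strut_graft_every_offset_valid(self):
        g = Mask2D(np.zeros((20, 30), bool), 1.0, periodic_al=True)
        f = Mask2D(np.ones((5, 5), bool), 1.0)
        valid = fp.search_alignments(g, f)
        assert len(valid) == 30 * (20 - 5 + 1)

    def test_single_strut_row_single_pixel_fen(self):
        g = np.zeros((10, 12), bool)
        g[4] = True
        f = np.zeros((1, 1), bool)
        f[0, 0] = True
        valid = fp.search_alignments(Mask2D(g, 1.0, periodic_al=True),
                                     Mask2D(f, 1.0))
        assert valid == {(a, p) for a in range(12) for p in range(10) if p != 4}

    def test_empty_fenestration_rejected(self):
        g = Mask2D(np.zeros((10, 10), bool), 1.0)
        f = Mask2D(np.zeros((2, 2), bool), 1.0)
        with pytest.raises(InputError):
            fp.search_alignments(g, f)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_on_random_masks(self, seed):
        g, f = random_masks(seed)
        m = search.overlap_map(g, f)
        brute = brute_overlap_map(g.pixels, f.pixels)
        assert np.array_equal(m, brute)

    def test_valid_set_shifts_with_graft_roll(self):
        g, f = random_masks(99)
        valid = fp.search_alignments(g, f)
        k = 17
        g2 = Mask2D(np.roll(g.pixels, k, axis=1), 1.0, periodic_al=True,
                    period_mm=g.period_mm)
        valid2 = fp.search_alignments(g2, f)
        shifted = {((a + k) % g.n_cols, p) for a, p in valid}
        assert valid2 == shifted


def _specs(period):
    return [
        FenestrationSpec("CA", 355.0, 355.0 / 360 * period, 21.0, 7.0, True),
        FenestrationSpec("SMA", 10.0, 10.0 / 360 * period, 30.0, 7.0, True),
        FenestrationSpec("RRA", 265.0, 265.0 / 360 * period, 54.0, 6.0, False),
        FenestrationSpec("LRA", 95.0, 95.0 / 360 * period, 57.0, 6.0, False),
    ]


class TestSelectOptimal:
    def test_zero_offset_preferred(self):
        period = np.pi * 24
        specs = _specs(period)
        fen = build_fenestration_mask(specs, 0.5, period)
        g = Mask2D(np.zeros((232, fen.n_cols), bool), 0.5, periodic_al=True,
                   period_mm=period)
        p_nom = int(round(fen.origin[1] / 0.5))
        fit = fp.select_optimal({(0, p_nom), (10, p_nom), (0, p_nom + 8)},
                                specs, fen, g)
        assert fit.offset_px == (0, p_nom)
        assert fit.total_deviation == pytest.approx(0.0)

    def test_deviation_is_pythagorean(self):
        period = np.pi * 24
        specs = _specs(period)[:1]
        fen = build_fenestration_mask(specs, 0.5, period)
        g = Mask2D(np.zeros((232, fen.n_cols), bool), 0.5, periodic_al=True,
                   period_mm=period)
        p_nom = int(round(fen.origin[1] / 0.5))
        fit = fp.select_optimal({(6, p_nom + 8)}, specs, fen, g)   # 3 mm, 4 mm
        assert fit.deviations["CA"] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_argmin_matches_exhaustive_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        period = np.pi * 24
        specs = _specs(period)
        fen = build_fenestration_mask(specs, 0.5, period)
        g = Mask2D(np.zeros((232, fen.n_cols), bool), 0.5, periodic_al=True,
                   period_mm=period)
        n_p = g.n_rows - fen.n_rows + 1
        offs = {(int(rng.integers(0, g.n_cols)), int(rng.integers(0, n_p)))
                for _ in range(40)}
        fit = fp.select_optimal(offs, specs, fen, g)
        # exhaustive oracle
        def total(o):
            dal = (o[0] * 0.5) % period
            dal = dal - period if dal > period / 2 else dal
            dpgd = o[1] * 0.5 - fen.origin[1]
            return len(specs) * np.hypot(dal, dpgd)
        best = min(total(o) for o in offs)
        assert fit.total_deviation == pytest.approx(best)

    def test_empty_set_raises(self):
        period = np.pi * 24
        specs = _specs(period)
        fen = build_fenestration_mask(specs, 0.5, period)
        g = Mask2D(np.zeros((232, fen.n_cols), bool), 0.5, periodic_al=True,
                   period_mm=period)
        with pytest.raises(NoValidFitError):
            fp.select_optimal(set(), specs, fen, g)

    def test_optimum_monotone_under_superset(self):
        period = np.pi * 24
        specs = _specs(period)
        fen = build_fenestration_mask(specs, 0.5, period)
        g = Mask2D(np.zeros((232, fen.n_cols), bool), 0.5, periodic_al=True,
                   period_mm=period)
        p_nom = int(round(fen.origin[1] / 0.5))
        small = {(30, p_nom + 10), (40, p_nom + 4)}
        big = small | {(2, p_nom + 1)}
        f1 = fp.select_optimal(small, specs, fen, g)
        f2 = fp.select_optimal(big, specs, fen, g)
        assert f2.total_deviation <= f1.total_deviation


class TestRelaxedSearch:
    def test_blocked_renal_clears_with_posterior_shift(self):
        adv = fp.generate_adversarial("blocked_renal", seed=3)
        fit = fp.relaxed_search(adv.graft_mask, adv.specs)
        assert fit.valid and fit.relaxed
        assert adv.shift_vessel in fit.per_vessel_shift
        dal, dpgd = fit.per_vessel_shift[adv.shift_vessel]
        assert abs(dal) <= search.MAX_POSTERIOR_SHIFT + 1e-9
        assert dpgd == 0.0
        # prioritized vessels stay rigid
        assert all(v not in fit.per_vessel_shift for v in ("CA", "SMA"))

    def test_fully_blocked_returns_invalid(self):
        adv = fp.generate_adversarial("no_fit")
        fit = fp.relaxed_search(adv.graft_mask, adv.specs)
        assert not fit.valid
        assert fit.overlap_pixels > 0

    def test_zero_max_shift_equals_rigid_search(self):
        period = np.pi * 24
        specs = _specs(period)
        g = fp.flatten_uniform(fp.load_repository()["thoracic-straight-26"],
                               0.5, deployed_diameter=24.0)
        rigid = fp.rigid_search(g, specs)
        relaxed = fp.relaxed_search(g, specs, max_posterior_shift=0.0)
        assert relaxed.valid
        assert relaxed.offset_px == rigid.offset_px
        assert relaxed.per_vessel_shift == {}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_over_offset_and_shift_grid(self, seed):
        """Constructed near-miss: thin strut bars block the renals at their
        nominal rows; compare against exhaustive (offset x shift) search."""
        rng = np.random.default_rng(seed)
        res = 0.5
        period = np.pi * 24
        specs = _specs(period)
        fen = build_fenestration_mask(specs, res, period)
        n_cols = fen.n_cols
        pixels = np.zeros((140, n_cols), bool)
        # random thin bars in the renal PGD band
        for _ in range(6):
            r = int(rng.integers(100, 130))
            c = int(rng.integers(0, n_cols))
            w = int(rng.integers(2, 10))
            cols = np.arange(c, c + w) % n_cols
            pixels[r:r + 3, cols] = True
        g = Mask2D(pixels, res, periodic_al=True, period_mm=period)
        fit = fp.relaxed_search(g, specs, max_posterior_shift=2.0)

        # brute force
        max_px = int(2.0 / res)
        movable = [sp for sp in specs if not sp.prioritized]
        best = None
        for s_r in range(max_px + 1):
            for s_l in range(max_px + 1):
                shifts = {"RRA": -s_r * res, "LRA": s_l * res}
                shifted = []
                for sp in specs:
                    sh = shifts.get(sp.vessel, 0.0)
                    shifted.append(FenestrationSpec(
                        sp.vessel, sp.phi, sp.al + sh, sp.pgd, sp.diameter,
                        sp.prioritized))
                fen_s = build_fenestration_mask(shifted, res, period)
                m = brute_overlap_map(g.pixels, fen_s.pixels)
                # offsets valid relative to this canvas's own origin
                for p, a in zip(*np.nonzero(m == 0)):
                    dal = (a * res) % period
                    dal = dal - period if dal > period / 2 else dal
                    dpgd = p * res - fen_s.origin[1]
                    tot = sum(np.hypot(dal + shifts.get(sp.vessel, 0.0), dpgd)
                              for sp in specs)
                    if best is None or tot < best - 1e-9:
                        best = tot
        if best is None:
            assert not fit.valid
        else:
            assert fit.valid
            assert fit.total_deviation == pytest.approx(best, abs=1e-6)
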