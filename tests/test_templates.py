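"""Graft template validation and mask flattening, checked against a
per-pixel rasterization oracle that samples the zigzag curve directly."""

import numpy as np
import pytest

import fenplan as fp
from fenplan.errors import DescriptorError, ParameterError, ValidationError
from fenplan.templates import flatten_tapered, flatten_uniform, zigzag_segments


def _oracle_strut_mask(template, diameter_prox, diameter_dist, resolution, margin):
    """Independent per-pixel rasterization: nested loops over pixels,
    distance to a densely sampled zigzag polyline (periodic copies)."""
    L = template.length
    if diameter_prox == diameter_dist:
        def circ(z):
            return np.pi * diameter_prox
        n_cols = int(round(np.pi * diameter_prox / resolution))
    else:
        def circ(z):
            f = min(max(z / L, 0.0), 1.0)
            return np.pi * (diameter_prox + f * (diameter_dist - diameter_prox))
        n_cols = int(round(np.pi * max(diameter_prox, diameter_dist) / resolution))
    n_rows = int(round(L / resolution))
    r = template.strut_wire_width / 2.0 + margin
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    # dense polyline samples of every ring, in (al, z)
    pts = []
    npk = template.n_peaks_per_ring
    for zc in template.ring_axial_positions:
        half = template.strut_amplitude / 2.0
        th_ap = np.arange(2 * npk + 1) / (2.0 * npk)
        z_ap = np.where(np.arange(2 * npk + 1) % 2 == 0, zc - half, zc + half)
        for k in range(2 * npk):
            t = np.linspace(0, 1, 60)
            th = th_ap[k] + t * (th_ap[k + 1] - th_ap[k])
            z = z_ap[k] + t * (z_ap[k + 1] - z_ap[k])
            for shift in (-1.0, 0.0, 1.0):
                c = np.array([circ(zz) for zz in z])
                pts.append(np.column_stack([(th + shift) * c, z]))
    pts = np.vstack(pts) if pts else np.zeros((0, 2))
    for i in range(n_rows):
        z = (i + 0.5) * resolution
        for j in range(n_cols):
            al = (j + 0.5) * resolution
            if al > circ(z):
                mask[i, j] = True   # beyond local circumference (tapered)
                continue
            if len(pts):
                d = np.min(np.hypot(pts[:, 0] - al, pts[:, 1] - z))
                if d <= r:
                    mask[i, j] = True
    return mask


class TestMakeTemplate:
    def test_uniform_construction(self):
        t = fp.make_template({"length": 100, "D_prox": 30, "D_dist": 30,
                              "rings": 5, "amplitude": 12, "wire": 0.5,
                              "peaks": 8, "positions": [10, 30, 50, 70, 90]})
        assert not t.tapered
        assert t.n_strut_rings == 5

    def test_tapered_flag_from_diameters(self):
        t = fp.make_template({"length": 100, "D_prox": 34, "D_dist": 30,
                              "amplitude": 12, "wire": 0.5, "peaks": 8,
                              "positions": [10, 90]})
        assert t.tapered

    def test_ring_outside_graft_rejected(self):
        with pytest.raises(ValidationError):
            fp.make_template({"length": 100, "D_prox": 30, "D_dist": 30,
                              "amplitude": 12, "wire": 0.5, "peaks": 8,
                              "positions": [10, 110]})

    def test_missing_key_rejected(self):
        with pytest.raises(DescriptorError):
            fp.make_template({"length": 100, "D_prox": 30})

    def test_wire_wider_than_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            fp.make_template({"length": 100, "D_prox": 30, "D_dist": 30,
                              "amplitude": 1.0, "wire": 2.0, "peaks": 8,
                              "positions": [50]})

    def test_repository_loads_bundled_templates(self):
        repo = fp.load_repository()
        assert "thoracic-straight-26" in repo
        assert repo["thoracic-tapered-30-26"].tapered


class TestFlattenUniform:
    def test_unrolled_dimensions(self, uniform_template):
        m = flatten_uniform(uniform_template, 0.5)
        assert m.pixels.shape == (200, round(np.pi * 30 / 0.5))
        assert m.periodic_al
        assert m.period_mm == pytest.approx(np.pi * 30)

    def test_zero_rings_gives_empty_mask(self):
        t = fp.make_template({"length": 50, "D_prox": 24, "D_dist": 24,
                              "amplitude": 8, "wire": 0.4, "peaks": 6,
                              "positions": []})
        assert not flatten_uniform(t, 0.5).pixels.any()

    def test_bad_resolution_rejected(self, uniform_template):
        with pytest.raises(ParameterError):
            flatten_uniform(uniform_template, 0.0)

    def test_tapered_template_rejected(self, tapered_template):
        with pytest.raises(ValidationError):
            flatten_uniform(tapered_template)

    def test_matches_per_pixel_oracle(self):
        t = fp.make_template({"length": 40, "D_prox": 20, "D_dist": 20,
                              "amplitude": 8, "wire": 0.6, "peaks": 5,
                              "positions": [10, 30]})
        m = flatten_uniform(t, 1.0, margin=1.0)
        oracle = _oracle_strut_mask(t, 20, 20, 1.0, 1.0)
        # dense-sample oracle vs exact segment distance: identical up to
        # boundary pixels within sampling slack
        assert np.mean(m.pixels != oracle) < 0.005

    def test_width_tracks_circumference_within_one_pixel(self, uniform_template):
        for res in (0.25, 0.4):
            m = flatten_uniform(uniform_template, res)
            assert abs(m.al_extent - np.pi * 30) <= res

    def test_ring_symmetry_under_peak_period_translation(self):
        # choose resolution so one zigzag period is an integer pixel count
        t = fp.make_template({"length": 40, "D_prox": 80 / np.pi, "D_dist": 80 / np.pi,
                              "amplitude": 8, "wire": 0.6, "peaks": 8,
                              "positions": [20]})
        m = flatten_uniform(t, 0.5)   # 160 cols, period 20 px
        assert m.n_cols == 160
        assert np.array_equal(m.pixels, np.roll(m.pixels, 20, axis=1))

    def test_downsampling_consistency(self):
        t = fp.make_template({"length": 40, "D_prox": 20, "D_dist": 20,
                              "amplitude": 8, "wire": 0.6, "peaks": 5,
                              "positions": [10, 30]})
        coarse = flatten_uniform(t, 1.0).pixels
        fine = flatten_uniform(t, 0.5).pixels
        h, w = coarse.shape
        fine = fine[:2 * h, :2 * w]
        blocks = fine.reshape(h, 2, -1, 2).swapaxes(1, 2).reshape(h, -1, 4)
        down = blocks.sum(axis=2) >= 2   # majority vote
        assert np.mean(down != coarse) <= 0.02


class TestFlattenTapered:
    def test_row_extent_tracks_local_circumference(self):
        t = fp.make_template({"length": 100, "D_prox": 34, "D_dist": 30,
                              "amplitude": 12, "wire": 0.5, "peaks": 8,
                              "positions": []})
        m = flatten_tapered(t, 0.5)
        valid_cols = (~m.pixels).sum(axis=1) * m.resolution
        pgd = (np.arange(m.n_rows) + 0.5) * m.resolution
        expected = np.pi * (34 + (30 - 34) * pgd / 100)
        assert np.all(np.abs(valid_cols - expected) <= 2 * m.resolution)

    def test_widening_taper_also_handled(self):
        t = fp.make_template({"length": 100, "D_prox": 30, "D_dist": 34,
                              "amplitude": 12, "wire": 0.5, "peaks": 8,
                              "positions": []})
        m = flatten_tapered(t, 0.5)
        valid_cols = (~m.pixels).sum(axis=1)
        assert valid_cols[-1] > valid_cols[0]

    def test_zero_taper_defers_to_uniform(self, uniform_template):
        m1 = flatten_tapered(uniform_template, 0.5,
                             deployed_diameters=(30.0, 30.0))
        m2 = flatten_uniform(uniform_template, 0.5)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_matches_per_pixel_oracle_on_frustum(self):
        t = fp.make_template({"length": 40, "D_prox": 22, "D_dist": 18,
                              "amplitude": 8, "wire": 0.6, "peaks": 5,
                              "positions": [10, 30]})
        m = flatten_tapered(t, 1.0, margin=1.0)
        oracle = _oracle_strut_mask(t, 22, 18, 1.0, 1.0)
        assert np.mean(m.pixels != oracle) < 0.01


def test_zigzag_segments_span_one_ring():
    t = fp.make_template({"length": 40, "D_prox": 20, "D_dist": 20,
                          "amplitude": 8, "wire": 0.6, "peaks": 5,
                          "positions": [20]})
    a, b = zigzag_segments(t, np.pi * 20, 0)
    z = np.concatenate([a[:, 1], b[:, 1]])
    assert z.min() == pytest.approx(16.0)
    assert z.max() == pytest.approx(24.0)
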