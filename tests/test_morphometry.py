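import numpy as np
import pytest

from ccmorph.io import Calibration
from ccmorph.morphometry import (analyze_mask, classify_fibers,
                                 compute_variables, measure_widths,
                                 measure_widths_raycast, skeletonize_mask)
from conftest import bar_mask, make_mask

PITCH = 400.0 / 384.0


class TestSkeletonizeMask:
    def test_empty_mask_gives_empty_graph(self):
        g = skeletonize_mask(make_mask(np.zeros((50, 50))))
        assert g.n_nodes == 0 and g.edges == []

    def test_horizontal_bar_single_edge(self):
        mask = bar_mask(height=3, width=100)
        g = skeletonize_mask(mask, prune_um=0)
        assert len(g.edges) == 1
        assert sorted(g.node_kind) == ["endpoint", "endpoint"]
        pitch = mask.calibration.pixel_pitch_um
        assert g.total_length_um == pytest.approx(99 * pitch, abs=2 * pitch)

    def test_t_shape_one_junction_three_endpoints(self):
        m = np.zeros((60, 60), dtype=bool)
        m[30, 5:55] = True   # horizontal stroke
        m[5:30, 30] = True   # vertical stroke meeting it
        g = skeletonize_mask(make_mask(m), prune_um=0)
        kinds = sorted(g.node_kind)
        assert kinds.count("endpoint") == 3
        assert kinds.count("junction") == 1
        assert len(g.edges) == 3

    def test_every_pixel_in_exactly_one_edge_or_node(self):
        m = np.zeros((60, 60), dtype=bool)
        m[30, 5:55] = True
        m[5:30, 30] = True
        g = skeletonize_mask(make_mask(m), prune_um=0)
        interior = [tuple(p) for e in g.edges for p in e.path[1:-1]]
        assert len(interior) == len(set(interior))

    def test_spur_pruning_removes_short_terminal_twig(self):
        m = np.zeros((60, 80), dtype=bool)
        m[30, 5:75] = True
        m[27:30, 40] = True   # 3-px twig off the line
        g0 = skeletonize_mask(make_mask(m), prune_um=0)
        g1 = skeletonize_mask(make_mask(m), prune_um=6.0)
        assert len(g0.edges) > len(g1.edges)
        # after pruning the line reads as one clean main fiber
        fs = classify_fibers(g1)
        assert len(fs.main_fibers) == 1
        assert fs.branches == [] and fs.orphans == []
        pitch = 400.0 / 384.0
        assert g1.total_length_um == pytest.approx(69 * pitch, abs=3 * pitch)


class TestClassifyFibers:
    def test_single_long_edge_is_one_main(self):
        g = skeletonize_mask(bar_mask(height=3, width=100), prune_um=0)
        fs = classify_fibers(g)
        assert len(fs.main_fibers) == 1
        assert fs.branches == [] and fs.orphans == []

    def test_main_with_two_stubs(self):
        m = np.zeros((100, 400), dtype=bool)
        m[50, 5:395] = True
        m[15:50, 100] = True    # 35-px stub
        m[50:90, 250] = True    # 40-px stub
        g = skeletonize_mask(make_mask(m), prune_um=0)
        fs = classify_fibers(g)
        assert len(fs.main_fibers) == 1
        assert len(fs.branches) == 2

    def test_x_crossing_two_mains_no_branches(self):
        m = np.zeros((101, 101), dtype=bool)
        for i in range(101):
            m[i, i] = True
            m[100 - i, i] = True
        g = skeletonize_mask(make_mask(m), prune_um=0)
        fs = classify_fibers(g)
        assert len(fs.main_fibers) == 2
        assert len(fs.branches) == 0

    def test_short_free_segment_is_not_a_main(self):
        g = skeletonize_mask(bar_mask(height=1, width=20), prune_um=0)
        fs = classify_fibers(g, main_min_length_um=50.0)
        assert fs.main_fibers == []
        assert len(fs.orphans) == 1


class TestMeasureWidths:
    def test_one_pixel_line_width_one(self):
        mask = bar_mask(height=1)
        g = skeletonize_mask(mask, prune_um=0)
        w = measure_widths(mask, g)
        assert (w.widths_px == 1).all()

    def test_five_row_bar_width_five(self):
        mask = bar_mask(height=5)
        g = skeletonize_mask(mask, prune_um=0)
        w = measure_widths(mask, g)
        interior = w.widths_px[(w.pixels[:, 1] > 20) & (w.pixels[:, 1] < 100)]
        assert np.median(interior) == 5

    def test_twenty_row_bar_clamped_to_eight(self):
        mask = bar_mask(height=20, shape=(60, 120))
        g = skeletonize_mask(mask, prune_um=0)
        w = measure_widths(mask, g)
        assert w.widths_px.max() == 8

    @pytest.mark.parametrize("height", [1, 3, 5, 7])
    def test_raycast_agrees_with_distance_transform_on_bars(self, height):
        mask = bar_mask(height=height)
        g = skeletonize_mask(mask, prune_um=0)
        w_edt = measure_widths(mask, g)
        w_ray = measure_widths_raycast(mask, g)
        sel = (w_ray.pixels[:, 1] > 20) & (w_ray.pixels[:, 1] < 100)
        assert abs(np.median(w_ray.widths_px[sel]) - height) <= 1
        sel_e = (w_edt.pixels[:, 1] > 20) & (w_edt.pixels[:, 1] < 100)
        assert abs(np.median(w_edt.widths_px[sel_e])
                   - np.median(w_ray.widths_px[sel])) <= 1


class TestComputeVariables:
    def test_empty_mask_all_zero(self):
        var, fs, wp = analyze_mask(make_mask(np.zeros((384, 384))))
        assert var.nfd == var.nbd == var.nfl == 0
        assert var.nfa_wxl == var.nfa_fiji == var.mean_width_um == 0

    def test_full_field_fiber_hand_values(self):
        """One 3-px-wide fiber across the 400 µm field: NFD = 1/0.16 = 6.25,
        NFL ≈ 0.4/0.16 = 2.5 mm/mm², NFA WxL ≈ 3 px · pitch · 400 µm / 0.16
        ≈ 7812 µm²/mm², mean width 3 px ≈ 3.125 µm."""
        m = np.zeros((384, 384), dtype=bool)
        m[191:194, :] = True
        var, fs, wp = analyze_mask(make_mask(m), prune_um=0)
        assert var.nfd == pytest.approx(6.25)
        assert var.nfl == pytest.approx(2.5, rel=0.02)
        assert var.nfa_wxl == pytest.approx(7812, rel=0.02)
        assert var.mean_width_um == pytest.approx(3.125, rel=0.02)

    def test_mean_width_is_nfa_wxl_over_nfl_identity(self):
        import ccmorph as cm
        img, _ = cm.generate_plexus(cm.random_plexus(11))
        var, fs, wp = analyze_mask(cm.segment_nerves(img))
        assert var.mean_width_um == pytest.approx(
            var.nfa_wxl / (1000.0 * var.nfl), rel=1e-12)

    def test_nfl_additive_over_disjoint_masks(self):
        a = np.zeros((384, 384), dtype=bool)
        b = np.zeros((384, 384), dtype=bool)
        a[100, 10:300] = True
        b[250:253, 50:350] = True
        va, *_ = analyze_mask(make_mask(a), prune_um=0)
        vb, *_ = analyze_mask(make_mask(b), prune_um=0)
        vab, *_ = analyze_mask(make_mask(a | b), prune_um=0)
        assert vab.nfl == pytest.approx(va.nfl + vb.nfl, rel=1e-9)

    def test_variables_invariant_under_mirror(self):
        """Counts are exactly mirror-invariant; skeleton-based lengths agree
        to the sub-percent asymmetry of the thinning pass."""
        import ccmorph as cm
        img, _ = cm.generate_plexus(cm.random_plexus(5))
        m = cm.segment_nerves(img)
        v1, *_ = analyze_mask(m)
        v2, *_ = analyze_mask(make_mask(m.mask[:, ::-1].copy(),
                                        m.calibration))
        assert v2.nfd == v1.nfd and v2.nbd == v1.nbd
        assert v2.nfa_fiji == pytest.approx(v1.nfa_fiji, rel=1e-12)
        for f in ("nfl", "nfa_wxl", "mean_width_um"):
            assert getattr(v2, f) == pytest.approx(getattr(v1, f), rel=5e-3)

    def test_literal_product_variant_is_inflated(self):
        m = np.zeros((384, 384), dtype=bool)
        m[191:194, :] = True
        mask = make_mask(m)
        g = skeletonize_mask(mask, prune_um=0)
        fs = classify_fibers(g)
        wp = measure_widths(mask, g)
        lit = compute_variables(fs, wp, mask, literal_wxl=True)
        std = compute_variables(fs, wp, mask)
        assert lit.nfa_wxl > 50 * std.nfa_wxl

    def test_calibration_mismatch_raises(self):
        mask = bar_mask(height=3)
        g = skeletonize_mask(mask, prune_um=0)
        fs = classify_fibers(g)
        wp = measure_widths(mask, g)
        other = make_mask(mask.mask, Calibration(2.0, mask.mask.shape[1],
                                                 mask.mask.shape[0]))
        with pytest.raises(ValueError):
            compute_variables(fs, wp, other)
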