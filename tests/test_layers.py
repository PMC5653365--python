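"""Layer-boundary segmentation: gradients, edge weights, shortest path,
RPE flattening."""

import numpy as np
import pytest

from octfluid import (BoundaryCurve, InvalidInputError, LayerParams,
                      flatten_rpe, generate_bscan, ilm_edge_weight, make_spec,
                      rpe_edge_weight, segment_layers, shortest_boundary,
                      to_ns_proposed, vertical_gradient)
from octfluid.layers import WEIGHT_EPS, _mean_above, _mean_below

from oracles import enumerate_shortest_path


def step_image(n_rows=8, n_cols=12, step_row=4, low=0.0, high=1.0):
    img = np.full((n_rows, n_cols), low)
    img[step_row:] = high
    return img


class TestVerticalGradient:
    def test_constant_image_gives_zero(self):
        assert np.all(vertical_gradient(np.full((6, 6), 0.3)) == 0.0)

    def test_ideal_step_reaches_kernel_maximum(self):
        img = step_image()
        grad = vertical_gradient(img, "dark_to_bright")
        assert grad[4].max() == pytest.approx(2.0)  # 2 * MaxG
        np.testing.assert_allclose(vertical_gradient(img, "bright_to_dark")[4],
                                   -2.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InvalidInputError):
            vertical_gradient(np.zeros((2, 6)))


class TestColumnMeans:
    @pytest.mark.parametrize("window", [1, 3, 10])
    def test_matches_naive_loops(self, rng, window):
        img = rng.random((9, 4))
        above = _mean_above(img, window)
        below = _mean_below(img, window)
        for r in range(9):
            for c in range(4):
                ra = img[max(0, r - window):r, c]
                rb = img[r + 1:r + 1 + window, c]
                assert above[r, c] == pytest.approx(ra.mean() if ra.size else img[0, c])
                assert below[r, c] == pytest.approx(rb.mean() if rb.size else img[-1, c])


class TestIlmWeight:
    def test_ideal_step_with_dark_background_is_minimal(self):
        img = step_image()
        grad = vertical_gradient(img, "dark_to_bright")
        w = ilm_edge_weight((4, 5), (4, 6), grad, img)
        assert w == pytest.approx(WEIGHT_EPS)  # 4 - 2 - 2 + 0, clipped

    def test_bright_tissue_above_is_penalized(self):
        # maximal gradient but mean(R) = MaxG -> weight exactly 2 * MaxG
        img = np.ones((8, 12))
        grad = np.full((8, 12), 2.0)
        w = ilm_edge_weight((4, 5), (4, 6), grad, img)
        assert w == pytest.approx(2.0)

    def test_flat_image_weight_is_maximal_for_its_column(self):
        img = np.full((8, 12), 0.5)
        grad = vertical_gradient(img)
        w = ilm_edge_weight((4, 5), (4, 6), grad, img)
        assert w == pytest.approx(4.0 + 2 * 0.5)

    def test_non_neighbors_rejected(self):
        img = step_image()
        grad = vertical_gradient(img)
        with pytest.raises(InvalidInputError):
            ilm_edge_weight((0, 0), (0, 5), grad, img)


class TestRpeWeight:
    def test_distance_term_isolated(self):
        # zero gradient, identical U-sets: weight difference is beta*(D2-D1)
        img = np.full((20, 6), 0.4)
        grad = np.zeros_like(img)
        ilm = BoundaryCurve(np.zeros(6), "ILM")
        params = LayerParams(beta=0.004)
        w_shallow = rpe_edge_weight((5, 2), (5, 3), grad, img, ilm, params)
        w_deep = rpe_edge_weight((15, 2), (15, 3), grad, img, ilm, params)
        assert w_shallow - w_deep == pytest.approx(0.004 * 10)

    def test_hand_evaluated_toy_grid(self, rng):
        img = rng.random((6, 6))
        grad = vertical_gradient(img, "bright_to_dark")
        ilm = BoundaryCurve(np.ones(6), "ILM")
        params = LayerParams(U_window=2, beta=0.01)
        p1, p2 = (3, 2), (4, 3)
        u = img[4:6, 2].mean()
        expect = 4.0 - grad[p1] - grad[p2] - u - 0.01 * (3 - 1)
        assert rpe_edge_weight(p1, p2, grad, img, ilm, params) == \
            pytest.approx(max(expect, WEIGHT_EPS))

    def test_choroid_below_beats_fluid_below(self):
        # Property-1 geometry: same gradient, U under the true RPE lies in
        # bright choroid (reflectivity), U under the decoy lies in dark fluid,
        # and the true RPE is deeper -> smaller weight
        img = np.full((30, 8), 0.0)
        img[10:14] = 0.08   # fluid band (reflectivity)
        img[20:24] = 0.25   # choroid band
        grad = np.zeros_like(img)
        ilm = BoundaryCurve(np.zeros(8), "ILM")
        w_decoy = rpe_edge_weight((9, 3), (9, 4), grad, img, ilm)
        w_true = rpe_edge_weight((19, 3), (19, 4), grad, img, ilm)
        assert w_true < w_decoy


class TestShortestBoundary:
    def test_matches_exhaustive_enumeration_on_random_grids(self, rng):
        for _ in range(10):
            table = {}

            def weight_fn(p1, p2):
                key = (p1, p2)
                if key not in table:
                    table[key] = float(rng.uniform(0.1, 1.0))
                return table[key]

            curve = shortest_boundary(weight_fn, (4, 4))
            _, expect = enumerate_shortest_path(weight_fn, (4, 4))
            np.testing.assert_array_equal(curve.rows, expect)

    def test_ideal_step_recovers_the_step_row(self):
        img = step_image(10, 14, step_row=6)
        grad = vertical_gradient(img, "dark_to_bright")

        def weight_fn(p1, p2):
            return ilm_edge_weight(p1, p2, grad, img)

        curve = shortest_boundary(weight_fn, img.shape)
        np.testing.assert_array_equal(curve.rows, np.full(14, 6))


class TestFlattenRpe:
    params = LayerParams(flatten_W=20, flatten_Tr=5, min_curvature=1.0)

    def test_flat_curve_is_identity(self):
        rpe = BoundaryCurve(np.full(60, 80.0), "RPE")
        out = flatten_rpe(rpe, self.params)
        np.testing.assert_array_equal(out.rows, rpe.rows)
        assert out.kind == "RPE_flattened"

    def test_tent_elevation_replaced_by_base_chord(self):
        x = np.arange(101)
        rows = 100.0 - np.maximum(0, 10 * (1 - np.abs(x - 50) / 15.0))
        out = flatten_rpe(BoundaryCurve(rows, "RPE"), self.params)
        np.testing.assert_allclose(out.rows, 100.0, atol=1e-9)

    def test_taller_of_two_bumps_flattened_first_then_both(self):
        x = np.arange(121)
        tall = np.maximum(0, 12 * (1 - np.abs(x - 45) / 12.0))
        small = np.maximum(0, 6 * (1 - np.abs(x - 85) / 10.0))
        rows = 120.0 - tall - small
        one_pass = LayerParams(flatten_W=20, flatten_Tr=5, min_curvature=1.0,
                               max_flatten_iters=1)
        out1 = flatten_rpe(BoundaryCurve(rows, "RPE"), one_pass)
        assert np.abs(out1.rows[33:58] - 120.0).max() < 1e-9  # tall bump gone
        assert np.abs(out1.rows[75:96] - 120.0).max() > 1.0   # small one remains
        out_all = flatten_rpe(BoundaryCurve(rows, "RPE"), self.params)
        np.testing.assert_allclose(out_all.rows, 120.0, atol=1e-9)

    def test_idempotent_on_flattened_curve(self):
        x = np.arange(101)
        rows = 100.0 - np.maximum(0, 10 * (1 - np.abs(x - 50) / 15.0))
        once = flatten_rpe(BoundaryCurve(rows, "RPE"), self.params)
        twice = flatten_rpe(once, self.params)
        np.testing.assert_array_equal(once.rows, twice.rows)

    def test_short_curve_rejected(self):
        with pytest.raises(InvalidInputError):
            flatten_rpe(BoundaryCurve(np.full(30, 10.0), "RPE"), self.params)


class TestSegmentLayers:
    def test_clean_phantom_recovered_within_tolerance(self, clean_phantom):
        ns = to_ns_proposed(clean_phantom.image)
        ilm, rpe_flat = segment_layers(ns)
        ilm_err = np.abs(ilm.rows - clean_phantom.true_ilm.rows)
        rpe_err = np.abs(rpe_flat.rows - clean_phantom.true_rpe_flat.rows)
        assert ilm_err.max() <= 1.0
        assert rpe_err.max() <= 2.0

    def test_monotone_step_and_layer_ordering(self, speckled_phantom):
        ns = to_ns_proposed(speckled_phantom.image)
        ilm, rpe_flat = segment_layers(ns)
        assert np.abs(np.diff(ilm.rows)).max() <= 1.0
        assert np.all(ilm.rows < rpe_flat.rows)

    def test_no_elevation_means_flattening_is_identity(self, clean_phantom):
        ns = to_ns_proposed(clean_phantom.image)
        ilm, rpe_flat, rpe_raw = segment_layers(ns, return_raw_rpe=True)
        np.testing.assert_array_equal(rpe_flat.rows, rpe_raw.rows)

    def test_subrpe_fluid_lies_above_flattened_rpe(self):
        truth = generate_bscan(make_spec("subrpe", rng_seed=11))
        ns = to_ns_proposed(truth.image)
        _, rpe_flat = segment_layers(ns)
        rr, cc = np.nonzero(truth.fluid_mask)
        assert np.all(rr <= rpe_flat.rows[cc])
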