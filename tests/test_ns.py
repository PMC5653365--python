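"""Neutrosophic-domain transforms: filter bank, lambda-correction, entropy."""

import numpy as np
import pytest

from octfluid import (DegenerateImageError, InvalidInputError,
                      InvalidParameterError, NSParams, build_filter_bank,
                      indeterminacy_entropy, lambda_correction,
                      to_ns_conventional, to_ns_proposed)


class TestFilterBank:
    def test_ten_orientations_cover_180_degrees(self):
        bank = build_filter_bank((3, 9), 10)
        assert len(bank.filters) == 10
        np.testing.assert_allclose(bank.orientations, np.arange(10) * 18.0)

    def test_kernels_are_mean_preserving_on_constant_input(self):
        bank = build_filter_bank((3, 9), 10)
        for k in bank.filters:
            assert k.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(k >= 0)

    def test_single_orientation_is_the_horizontal_base(self):
        bank = build_filter_bank((3, 9), 1)
        k = bank.filters[0]
        # horizontal: mass concentrated along the center row, symmetric
        np.testing.assert_allclose(k, k[::-1, :], atol=1e-12)
        np.testing.assert_allclose(k, k[:, ::-1], atol=1e-12)
        # elongated horizontally: central 3 rows carry almost all the mass
        mid = k.shape[0] // 2
        assert k[mid - 1:mid + 2].sum() > 0.99
        assert k[mid].sum() > 3 * k[:, mid].max()

    def test_quarter_turn_transposes_the_kernel(self):
        bank = build_filter_bank((3, 9), 2)  # 0 and 90 degrees
        np.testing.assert_allclose(bank.filters[1], bank.filters[0].T, atol=1e-12)

    @pytest.mark.parametrize("shape,n", [((0, 9), 10), ((3, -1), 10),
                                         ((9, 3), 10), ((3, 9), 0)])
    def test_invalid_parameters_rejected(self, shape, n):
        with pytest.raises(InvalidParameterError):
            build_filter_bank(shape, n)


class TestLambdaCorrection:
    def test_zero_indeterminacy_keeps_t(self, rng):
        T = rng.random((6, 10))
        FIs = [rng.random((6, 10)) for _ in range(3)]
        out = lambda_correction(T, np.zeros_like(T), FIs, 0.7)
        np.testing.assert_array_equal(out, T)

    def test_noisy_pixel_replaced_by_most_deviating_response(self):
        T = np.full((3, 9), 0.4)
        I = np.zeros_like(T)
        I[1, 4] = 1.0
        FIs = [np.full_like(T, v) for v in (0.2, 0.9, 0.5)]
        out = lambda_correction(T, I, FIs, 0.7)
        assert out[1, 4] == pytest.approx(0.9)  # argmax |0.4 - FI_k|
        assert out[0, 0] == pytest.approx(0.4)

    def test_threshold_is_strict(self):
        # I exactly at lambda falls into the replacement branch
        T = np.full((3, 9), 0.4)
        I = np.full_like(T, 0.7)
        FIs = [np.full_like(T, 0.9)]
        out = lambda_correction(T, I, FIs, 0.7)
        np.testing.assert_allclose(out, 0.9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            lambda_correction(np.zeros((3, 9)), np.zeros((3, 8)),
                              [np.zeros((3, 9))], 0.7)


class TestEntropy:
    def test_single_bin_occupancy_gives_zero(self):
        assert indeterminacy_entropy(np.full((5, 5), 0.42), 10) == 0.0

    def test_uniform_occupancy_gives_log_nbins(self):
        vals = (np.arange(10) + 0.5) / 10.0
        assert indeterminacy_entropy(vals, 10) == pytest.approx(np.log(10))

    def test_hand_computed_histogram(self):
        # counts {2, 1, 1} over 4 pixels -> -(1/2 ln 1/2 + 2 * 1/4 ln 1/4)
        vals = np.array([0.1, 0.1, 0.6, 0.9])
        assert indeterminacy_entropy(vals, 10) == pytest.approx(1.5 * np.log(2))

    def test_empty_array_rejected(self):
        with pytest.raises(InvalidInputError):
            indeterminacy_entropy(np.array([]))


class TestProposedTransform:
    def test_darkest_pixel_gets_full_membership(self, clean_phantom):
        ns = to_ns_proposed(clean_phantom.image)
        g = clean_phantom.image
        assert ns.T[np.unravel_index(np.argmin(g), g.shape)] == pytest.approx(1.0)

    def test_planes_in_unit_range_and_same_shape(self, speckled_phantom):
        ns = to_ns_proposed(speckled_phantom.image)
        assert ns.T.shape == ns.I.shape == speckled_phantom.image.shape
        for plane in (ns.T, ns.I):
            assert plane.min() >= 0.0 and plane.max() <= 1.0

    def test_monotone_inversion_of_intensity(self, clean_phantom):
        # darker pixel -> strictly higher membership (clean image, global norm)
        g = clean_phantom.image
        ns = to_ns_proposed(g)
        dark = g == g.min()
        bright = g == g.max()
        assert ns.T[dark].min() > ns.T[bright].max()

    def test_clean_input_returns_t_unchanged_by_correction(self):
        # piecewise-constant bands: I < lambda everywhere, so the entropy
        # loop terminates with T exactly the inverted normalized image
        g = np.full((40, 40), 0.6)
        g[:20] = 0.1
        ns = to_ns_proposed(g)
        expected = 1.0 - (g - 0.1) / 0.5
        np.testing.assert_allclose(ns.T, expected, atol=1e-12)

    def test_horizontal_edge_has_near_zero_indeterminacy(self):
        # on a horizontal step the horizontal filter reproduces T away from
        # the 3-row kernel reach, and I stays small even on the edge rows
        g = np.full((40, 60), 0.6)
        g[:20] = 0.1
        ns = to_ns_proposed(g)
        assert ns.I[19:21, 5:-5].max() < 0.35
        assert ns.I[[0, -1], :].max() < 1e-6

    def test_indeterminacy_low_away_from_region_borders(self):
        # noiseless piecewise-constant phantom: I ~ 0 everywhere except
        # within one kernel length (9 px) of the band borders
        g = np.full((60, 60), 0.55)
        g[:20] = 0.05
        g[45:] = 0.25
        ns = to_ns_proposed(g)
        interior = np.ones_like(g, dtype=bool)
        for edge in (20, 45):
            interior[edge - 9:edge + 9] = False
        assert ns.I[interior].max() < 1e-9

    def test_horizontal_edge_indeterminacy_below_conventional(self):
        # the stated motivation: oriented filters do not mark layer
        # boundaries as indeterminate, the square-window deviation does
        g = np.full((40, 60), 0.6)
        g[:20] = 0.1
        edge_rows = slice(19, 21)
        i_prop = to_ns_proposed(g).I[edge_rows].mean()
        i_conv = to_ns_conventional(g).I[edge_rows].mean()
        assert i_prop <= i_conv

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            to_ns_proposed(np.full((20, 20), 0.5))

    def test_entropy_loop_terminates_within_max_iters(self, rng):
        g = rng.random((40, 40))
        ns = to_ns_proposed(g, params=NSParams(max_iters=5))
        assert ns.T.shape == g.shape

    def test_local_mean_variant_smooths_t(self, speckled_phantom):
        g = speckled_phantom.image
        sharp = to_ns_proposed(g).T
        smooth = to_ns_proposed(g, params=NSParams(proposed_local_mean=True)).T
        # windowed-mean T varies less between neighbors than raw T
        assert np.abs(np.diff(smooth, axis=0)).mean() < np.abs(np.diff(sharp, axis=0)).mean()


class TestConventionalTransform:
    def test_darkest_local_mean_gets_full_membership(self, clean_phantom):
        from scipy.ndimage import uniform_filter

        g = clean_phantom.image
        ns = to_ns_conventional(g)
        gbar = uniform_filter(g, 11, mode="reflect")
        darkest = np.unravel_index(np.argmin(gbar), g.shape)
        assert ns.T[darkest] == pytest.approx(1.0, abs=1e-6)

    def test_salt_pixel_smoothed_by_alpha_mean(self):
        # a lone salt pixel holds the maximal deviation from its windowed
        # mean, hence maximal initial I, and the alpha-mean replaces its
        # membership by the windowed mean
        g = np.full((30, 30), 0.3)
        g[7, 11] = 1.0
        from scipy.ndimage import uniform_filter
        delta = np.abs(g - uniform_filter(g, 11, mode="reflect"))
        assert np.unravel_index(np.argmax(delta), g.shape) == (7, 11)
        ns = to_ns_conventional(g)
        # membership of the outlier ends close to its neighbors'
        assert abs(ns.T[7, 11] - ns.T[7, 20]) < 0.35

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            to_ns_conventional(np.full((20, 20), 0.3))

    def test_planes_stay_in_unit_range(self, speckled_phantom):
        ns = to_ns_conventional(speckled_phantom.image)
        for plane in (ns.T, ns.I):
            assert plane.min() >= 0.0 and plane.max() <= 1.0
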