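"""Unit and property tests for the per-pixel HSV classification model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tch import color_model as cm
from tch import CrownClass, ModelConstants, classify_array, classify_pixel

from oracle import classify_pixel_reference


class TestNormalization:
    @pytest.mark.parametrize("raw, expected", [
        ((255, 255, 255), (1.0, 1.0, 1.0)),
        ((0, 0, 0), (0.0, 0.0, 0.0)),
        ((51, 102, 204), (0.2, 0.4, 0.8)),
    ])
    def test_examples(self, raw, expected):
        assert cm.normalize_rgb(*raw) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("raw", [(-1, 0, 0), (0, 256, 0), (0.5, 1, 2)])
    def test_out_of_domain_rejected(self, raw):
        with pytest.raises(ValueError):
            cm.normalize_rgb(*raw)

    def test_16_bit(self):
        assert cm.normalize_rgb(65535, 0, 65535, bits=16) == (1.0, 0.0, 1.0)


class TestBlueAdjustment:
    def test_green_anchor_pixel_decremented(self):
        r, g, b = cm.apply_blue_adjustment(100 / 255, 101 / 255, 100 / 255)
        assert b == 100 / 255 - 1 / 256
        assert (r, g) == (100 / 255, 101 / 255)

    def test_red_anchor_pixel_decremented(self):
        _, _, b = cm.apply_blue_adjustment(101 / 255, 100 / 255, 100 / 255)
        assert b == 100 / 255 - 1 / 256

    def test_no_channel_equality_unchanged(self):
        assert cm.apply_blue_adjustment(0.2, 0.4, 0.8) == (0.2, 0.4, 0.8)

    def test_zero_blue_floored(self):
        assert cm.apply_blue_adjustment(0.0, 200 / 255, 0.0) == (0.0, 200 / 255, 0.0)

    def test_achromatic_pixel_not_adjusted(self):
        # all-equal pixels must reach the S = 0 branch untouched
        p = (0.5, 0.5, 0.5)
        assert cm.apply_blue_adjustment(*p) == p

    def test_bit_depth_scales_decrement(self):
        _, _, b = cm.apply_blue_adjustment(0.4, 0.5, 0.4, bits=16)
        assert b == 0.4 - 1 / 65536


class TestHsvConversion:
    @pytest.mark.parametrize("rgb, hsv", [
        ((0.0, 1.0, 0.0), (1 / 3, 1.0, 1.0)),
        ((0.5, 0.5, 0.5), (0.0, 0.0, 0.5)),
        ((180 / 255, 60 / 255, 50 / 255), (0.012821, 0.722222, 0.705882)),
    ])
    def test_examples(self, rgb, hsv):
        assert cm.rgb_to_hsv(*rgb) == pytest.approx(hsv, abs=1e-6)

    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
    def test_matches_skimage(self, r, g, b):
        """Cross-check the vectorized conversion against scikit-image."""
        from skimage.color import rgb2hsv
        arr = np.array([[[r, g, b]]], dtype=np.float64) / 255.0
        h, s, v = cm._rgb_to_hsv_array(arr[..., 0], arr[..., 1], arr[..., 2])
        ref = rgb2hsv(arr)[0, 0]
        assert h[0, 0] == pytest.approx(ref[0] % 1.0, abs=1e-12)
        assert s[0, 0] == pytest.approx(ref[1], abs=1e-12)
        assert v[0, 0] == pytest.approx(ref[2], abs=1e-12)


class TestHueRescaling:
    @pytest.mark.parametrize("h, hg", [(1 / 3, 1.0), (0.25, 0.5), (0.0, -1.0)])
    def test_green_examples(self, h, hg):
        assert cm.rescale_hue_green(h) == pytest.approx(hg, abs=1e-12)

    @pytest.mark.parametrize("h, hr", [(0.0, 1.0), (1 / 12, 0.5), (1 / 3, -1.0)])
    def test_red_examples(self, h, hr):
        assert cm.rescale_hue_red(h) == pytest.approx(hr, abs=1e-12)

    @given(st.floats(0.0, 1.0, exclude_max=True))
    def test_supports(self, h):
        """G support is exactly (1/6, 1/2); R support [0,1/6) u (5/6, 1)."""
        from hypothesis import assume
        # boundary hues sit on a float rounding knife edge; tested exactly below
        assume(all(abs(h - edge) > 1e-9 for edge in (1 / 6, 1 / 2, 5 / 6)))
        assert (cm.rescale_hue_green(h) > 0) == (1 / 6 < h < 1 / 2)
        assert (cm.rescale_hue_red(h) > 0) == (h < 1 / 6 or h > 5 / 6)

    def test_support_boundaries_are_zero_scores(self):
        """At the sixth-hue boundaries both rescaled hues give score 0."""
        for h in (1 / 6, 0.5):
            assert cm.score_green(cm.rescale_hue_green(h), 5.0) == \
                pytest.approx(0.0, abs=1e-12)
        for h in (1 / 6, 5 / 6):
            assert cm.score_red(cm.rescale_hue_red(h), 5.0) == \
                pytest.approx(0.0, abs=1e-12)

    @given(st.floats(0.0, 2 / 3))
    def test_green_symmetry(self, h):
        assert cm.rescale_hue_green(h) == pytest.approx(
            cm.rescale_hue_green(2 / 3 - h), abs=1e-12)

    @given(st.floats(0.0, 1.0))
    def test_red_symmetry(self, h):
        assert cm.rescale_hue_red(h) == pytest.approx(
            cm.rescale_hue_red(1.0 - h), abs=1e-12)


class TestScoreEquations:
    @pytest.mark.parametrize("fn, x, c, expected", [
        (cm.score_green, 1.0, 5.0, 1.0),
        (cm.score_green, 0.5, 5.0, (5 ** 0.5 - 1) / 4),
        (cm.score_red, -1.0, 5.0, 0.0),
        (cm.score_red, -1.0, 1e6, 0.0),
        (cm.score_gray, 0.0, 1e7, 1.0),
        (cm.score_gray, 1.0, 1e7, 0.0),
        (cm.score_gray, 0.3, 1e7, (1e7 ** 0.7 - 1) / (1e7 - 1)),
        (cm.score_shadow, 0.0, 1e4, 1.0),
        (cm.score_shadow, 0.5, 1e4, 99 / 9999),
        (cm.score_shadow, 20 / 255, 1e4, (1e4 ** (1 - 20 / 255) - 1) / 9999),
    ])
    def test_examples(self, fn, x, c, expected):
        assert fn(x, c) == pytest.approx(expected, rel=1e-12)

    def test_gray_example_value(self):
        # S = 0.3, c_y = 1e7 -> ~0.0079432
        assert cm.score_gray(0.3, 1e7) == pytest.approx(0.0079432, abs=1e-6)

    def test_shadow_example_value(self):
        # V = 20/255, c_d = 1e4 -> ~0.48561
        assert cm.score_shadow(20 / 255, 1e4) == pytest.approx(0.48561, abs=1e-4)

    @pytest.mark.parametrize("fn", [cm.score_green, cm.score_red,
                                    cm.score_gray, cm.score_shadow])
    def test_constant_below_two_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.5, 1.5)

    @given(st.floats(0.0, 1.0), st.floats(2.0, 1e8))
    def test_range_and_anchors(self, h, c):
        g = cm.score_green(h, c)
        assert 0.0 <= g <= 1.0
        if h == 1.0:
            assert g == 1.0
        if h == 0.0:
            assert g == 0.0

    @given(st.floats(2.0, 1e8))
    def test_monotone_decay_in_saturation(self, c):
        ss = np.linspace(0.0, 1.0, 33)
        ys = [cm.score_gray(s, c) for s in ss]
        assert all(a > b for a, b in zip(ys, ys[1:]))

    def test_c_equal_two_is_exponential_curve(self):
        for h in (0.0, 0.25, 0.5, 1.0):
            assert cm.score_green(h, 2.0) == pytest.approx(2 ** h - 1, rel=1e-12)

    def test_large_c_concentrates_score_at_anchor(self):
        # as c -> inf the curve collapses to 0 for any h < 1
        assert cm.score_green(0.9, 1e8) < 0.2
        assert cm.score_green(0.9, 1e8) < cm.score_green(0.9, 1e4)
        assert cm.score_green(1.0, 1e8) == 1.0


class TestModelConstants:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelConstants(c_g=1.0)
        with pytest.raises(ValueError):
            ModelConstants(t=-0.1)

    def test_replace(self, constants):
        assert constants.replace(t=0.2).t == 0.2
        assert constants.t == 0.1


class TestClassifyPixel:
    @pytest.mark.parametrize("rgb, expected", [
        ((76, 175, 80), CrownClass.GREEN),
        ((128, 128, 128), CrownClass.GRAY),
        ((10, 10, 10), CrownClass.SHADOW),
        ((180, 60, 50), CrownClass.RED),
        ((100, 101, 100), CrownClass.GRAY),
    ])
    def test_worked_examples(self, rgb, expected, constants):
        cls, _ = classify_pixel(*rgb, constants)
        assert cls is expected

    def test_worked_example_scores(self, constants):
        _, s = classify_pixel(76, 175, 80, constants)
        assert s.G == pytest.approx(0.921, abs=1e-3)
        _, s = classify_pixel(128, 128, 128, constants)
        assert s.Y == pytest.approx(0.990, abs=1e-3)
        _, s = classify_pixel(10, 10, 10, constants)
        assert s.D == pytest.approx(0.6966, abs=1e-3)
        assert s.Y == pytest.approx(0.3034, abs=1e-3)
        _, s = classify_pixel(180, 60, 50, constants)
        assert s.R == pytest.approx(0.8544, abs=1e-3)

    def test_blue_adjustment_purpose(self, constants):
        """(100,101,100) is gray with the adjustment, green without: the
        exact H = 1/3 anchor would otherwise dominate at any saturation."""
        with_adj, _ = classify_pixel(100, 101, 100, constants)
        without, scores = classify_pixel(100, 101, 100, constants,
                                         blue_adjustment=False)
        assert with_adj is CrownClass.GRAY
        assert without is CrownClass.GREEN
        assert scores.G == 1.0

    def test_below_threshold_unclassified(self, constants):
        # saturated blue: every score is ~0
        cls, scores = classify_pixel(0, 0, 255, constants)
        assert cls is CrownClass.UNCLASSIFIED
        assert scores.X <= constants.t

    def test_dark_achromatic_is_shadow_not_gray(self, constants):
        """The S=0 recalculation: near-black achromatic pixels must fall to
        shadow, never gray."""
        for val in range(0, 14):  # V <= 13/255 ~ 0.051
            cls, _ = classify_pixel(val, val, val, constants)
            assert cls is CrownClass.SHADOW, f"({val},)*3 -> {cls}"

    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
    @settings(max_examples=300)
    def test_matches_reference_oracle(self, r, g, b):
        code, (G, R, Y, D) = classify_pixel_reference(r, g, b)
        cls, scores = classify_pixel(r, g, b)
        assert int(cls) == code
        # the oracle uses libm pow, which may differ in the last ulp
        assert scores.G == pytest.approx(G, rel=1e-14, abs=1e-15)
        assert scores.R == pytest.approx(R, rel=1e-14, abs=1e-15)
        assert scores.Y == pytest.approx(Y, rel=1e-14, abs=1e-15)
        assert scores.D == pytest.approx(D, rel=1e-14, abs=1e-15)

    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255),
           st.sampled_from([2, 5, 100, 1e6]), st.sampled_from([2, 1e4, 1e8]))
    @settings(max_examples=200)
    def test_score_invariants(self, r, g, b, c_hue, c_sv):
        consts = ModelConstants(c_g=c_hue, c_r=c_hue, c_y=c_sv, c_d=c_sv)
        cls, s = classify_pixel(r, g, b, consts)
        assert 0.0 <= s.G <= 1.0 and 0.0 <= s.R <= 1.0 and 0.0 <= s.D <= 1.0
        assert -1.0 <= s.Y <= 1.0  # may dip negative only via the S=0 recalc
        assert isinstance(cls, CrownClass)  # exactly one of the five outcomes


class TestClassifyArray:
    def test_bit_identical_to_scalar(self, constants, rng):
        rgb = rng.integers(0, 256, size=(80, 80, 3), dtype=np.uint8)
        codes, (G, R, Y, D) = classify_array(rgb, constants, return_scores=True)
        for i in range(80):
            for j in range(80):
                cls, s = classify_pixel(*(int(v) for v in rgb[i, j]), constants)
                assert codes[i, j] == int(cls)
                assert (G[i, j], R[i, j], Y[i, j], D[i, j]) == \
                    (s.G, s.R, s.Y, s.D)

    def test_channel_equality_pixels(self, constants):
        """Pixels engineered to hit the blue-adjustment path."""
        rgb = np.array([[(100, 101, 100), (101, 100, 100),
                         (50, 50, 50), (0, 200, 0)]], dtype=np.uint8)
        codes = classify_array(rgb, constants)
        expected = [int(classify_pixel(*map(int, p), constants)[0])
                    for p in rgb[0]]
        assert codes[0].tolist() == expected

    def test_rejects_float_input(self, constants):
        with pytest.raises(ValueError):
            classify_array(np.zeros((2, 2, 3)), constants)

    def test_rejects_bad_shape(self, constants):
        with pytest.raises(ValueError):
            classify_array(np.zeros((2, 4), dtype=np.uint8), constants)

    def test_out_of_range_for_bit_depth(self, constants):
        arr = np.full((1, 1, 3), 300, dtype=np.uint16)
        with pytest.raises(ValueError):
            classify_array(arr, constants, bits=8)
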