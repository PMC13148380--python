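"""Unit and property tests of the GLCM texture core."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from stainstat import glcm

import oracles


class TestQuantize:
    def test_four_even_values_hit_four_levels(self):
        tile = np.array([[0.0, 1 / 3], [2 / 3, 1.0]])
        assert glcm.quantize(tile, 4).ravel().tolist() == [0, 1, 2, 3]

    def test_constant_tile_maps_to_zero(self):
        assert (glcm.quantize(np.full((4, 4), 0.7), 4) == 0).all()

    def test_max_value_clamped_below_n_gray(self):
        levels = glcm.quantize(np.linspace(0, 1, 17).reshape(1, -1), 4)
        assert levels.max() == 3

    @given(
        hnp.arrays(float, (5, 5), elements=st.floats(0, 1, width=32)),
        st.floats(-10, 10, allow_nan=False),
    )
    def test_shift_invariance(self, tile, const):
        # range-based bins: adding a constant never changes the levels
        np.testing.assert_array_equal(
            glcm.quantize(tile, 4), glcm.quantize(tile + const, 4)
        )

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            glcm.quantize(np.array([[0.0, np.nan]]), 4)


class TestCooccurrence:
    def test_hand_enumerated_two_by_two(self):
        P = glcm.cooccurrence(np.array([[0, 0], [1, 1]]), (0, 1), n_gray=2)
        np.testing.assert_allclose(P, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_levels_single_entry(self):
        P = glcm.cooccurrence(np.zeros((3, 3), dtype=int), (0, 1), n_gray=4)
        assert P[0, 0] == 1.0 and P.sum() == 1.0

    @given(hnp.arrays(np.intp, (4, 6), elements=st.integers(0, 3)))
    def test_normalized_and_symmetric(self, levels):
        for shift in glcm.DEFAULT_SHIFTS:
            P = glcm.cooccurrence(levels, shift, n_gray=4)
            assert np.isclose(P.sum(), 1.0)
            np.testing.assert_allclose(P, P.T)

    def test_error_when_no_pairs(self):
        with pytest.raises(ValueError, match="no pixel pairs"):
            glcm.cooccurrence(np.zeros((1, 1), dtype=int), (0, 1), n_gray=2)

    def test_matches_scikit_image(self, rng):
        # independent implementation cross-check (angle 0 == shift (0, 1))
        from skimage.feature import graycomatrix

        levels = rng.integers(0, 4, size=(9, 9))
        ours = glcm.cooccurrence(levels, (0, 1), n_gray=4)
        theirs = graycomatrix(
            levels.astype(np.uint8), [1], [0], levels=4, symmetric=True, normed=True
        )[:, :, 0, 0]
        np.testing.assert_allclose(ours, theirs)


class TestStatistics:
    def test_degenerate_distribution(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        s = glcm.glcm_statistics(P)
        assert s == {
            "mean": 0.0, "variance": 0.0, "contrast": 0.0, "dissimilarity": 0.0,
            "homogeneity": 1.0, "second_moment": 1.0, "entropy": 0.0,
        }

    def test_two_point_diagonal(self):
        s = glcm.glcm_statistics(np.diag([0.5, 0.5]))
        assert s["mean"] == 0.5 and s["variance"] == 0.25
        assert s["contrast"] == 0.0 and s["dissimilarity"] == 0.0
        assert s["homogeneity"] == 1.0 and s["second_moment"] == 0.5
        assert np.isclose(s["entropy"], math.log(2))

    def test_uniform_distribution(self):
        s = glcm.glcm_statistics(np.full((4, 4), 1 / 16))
        assert np.isclose(s["second_moment"], 1 / 16)
        assert np.isclose(s["entropy"], math.log(16))

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            glcm.glcm_statistics(np.ones((2, 2)))


def test_exhaustive_binary_images_match_oracle():
    """Pair-enumeration oracle equality on all 2^(3x3) binary images."""
    for bits in itertools.product((0, 1), repeat=9):
        levels = np.array(bits).reshape(3, 3)
        for shift in glcm.DEFAULT_SHIFTS:
            ours = glcm.cooccurrence(levels, shift, n_gray=2)
            ref = oracles.brute_cooccurrence(levels, shift, n_gray=2)
            np.testing.assert_array_equal(ours, ref)
        P = glcm.cooccurrence(levels, (0, 1), n_gray=2)
        ref_stats = oracles.brute_statistics(P)
        for k, v in glcm.glcm_statistics(P).items():
            assert np.isclose(v, ref_stats[k], atol=1e-12)


class TestTextureMap:
    def test_constant_tile_limits(self):
        tm = glcm.texture_map(np.full((6, 6), 0.3))
        v = tm.valid
        assert v.sum() == 16
        assert (tm.maps["homogeneity"][v] == 1.0).all()
        assert (tm.maps["entropy"][v] == 0.0).all()
        assert (tm.maps["contrast"][v] == 0.0).all()

    def test_matches_brute_force_per_window(self, rng):
        tile = rng.random((8, 10))
        cfg = glcm.GlcmConfig()
        tm = glcm.texture_map(tile, cfg)
        levels = glcm.quantize(tile, cfg.n_gray)
        for pr in range(1, 7):
            for pc in range(1, 9):
                P = oracles.brute_window_cooccurrence(
                    levels, pr, pc, cfg.window, cfg.shifts, cfg.n_gray
                )
                ref = oracles.brute_statistics(P)
                for name in glcm.STATISTIC_NAMES:
                    assert np.isclose(tm.maps[name][pr, pc], ref[name], atol=1e-10)

    def test_vertical_stripes_constant_interior_contrast(self, rng):
        tile = np.tile([0.0, 1.0], (7, 4))[:, :7]
        cfg = glcm.GlcmConfig()
        tm = glcm.texture_map(tile, cfg)
        levels = glcm.quantize(tile, 4)
        interior = tm.maps["contrast"][1:-1, 1:-1]
        assert np.allclose(interior, interior[0, 0])
        ref = oracles.brute_statistics(
            oracles.brute_window_cooccurrence(levels, 3, 3, 3, cfg.shifts, 4)
        )
        assert np.isclose(interior[1, 1], ref["contrast"])

    def test_windowing_differs_from_whole_tile_pooling(self, rng):
        # regression guard: per-window maps are not just the global GLCM
        tile = rng.random((10, 10))
        tm = glcm.texture_map(tile)
        levels = glcm.quantize(tile, 4)
        pooled = np.zeros((4, 4))
        for shift in glcm.DEFAULT_SHIFTS:
            pooled += oracles.brute_cooccurrence(levels, shift, 4)
        global_entropy = glcm.glcm_statistics(pooled / pooled.sum())["entropy"]
        assert not np.isclose(np.nanmean(tm.maps["entropy"]), global_entropy)

    def test_window_equal_to_tile_reproduces_whole_tile_stats(self, rng):
        tile = rng.random((7, 7))
        cfg = glcm.GlcmConfig(window=7)
        tm = glcm.texture_map(tile, cfg)
        assert tm.n_valid == 1
        levels = glcm.quantize(tile, 4)
        counts = np.zeros((4, 4))
        for shift in cfg.shifts:
            h, w = levels.shape
            dr, dc = shift
            for r in range(h):
                for c in range(w):
                    if 0 <= r + dr < h and 0 <= c + dc < w:
                        counts[levels[r, c], levels[r + dr, c + dc]] += 1
                        counts[levels[r + dr, c + dc], levels[r, c]] += 1
        ref = glcm.glcm_statistics(counts / counts.sum())
        for name in glcm.STATISTIC_NAMES:
            assert np.isclose(tm.maps[name][3, 3], ref[name])

    def test_rotation_invariance_of_sorted_maps(self, rng):
        tile = rng.random((9, 9))
        tm = glcm.texture_map(tile)
        tm_rot = glcm.texture_map(np.rot90(tile))
        for name in glcm.STATISTIC_NAMES:
            a = np.sort(tm.maps[name][tm.valid])
            b = np.sort(tm_rot.maps[name][tm_rot.valid])
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_statistic_bounds(self, rng):
        tile = rng.random((12, 12))
        tm = glcm.texture_map(tile)
        v = tm.valid
        assert ((tm.maps["homogeneity"][v] > 0) & (tm.maps["homogeneity"][v] <= 1)).all()
        assert ((tm.maps["second_moment"][v] > 0) & (tm.maps["second_moment"][v] <= 1)).all()
        assert ((tm.maps["entropy"][v] >= 0) & (tm.maps["entropy"][v] <= 2 * np.log(4))).all()
        assert (tm.maps["contrast"][v] <= 9).all()

    def test_tile_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            glcm.texture_map(np.zeros((2, 2)))


class TestSummarizeTile:
    def _map_from(self, values):
        arr = np.asarray(values, dtype=float).reshape(1, -1)
        maps = {name: arr for name in glcm.STATISTIC_NAMES}
        return glcm.TextureMap(maps=maps, valid=np.ones_like(arr, bool),
                               config=glcm.GlcmConfig())

    def test_constant_map_flags_moments(self):
        out = glcm.summarize_tile(self._map_from([0.4] * 6))
        assert out["mean_mean"] == pytest.approx(0.4) and out["mean_sd"] == 0.0
        assert out["mean_q1"] == 0.4 and out["mean_q3"] == 0.4
        assert np.isnan(out["mean_kurtosis"]) and np.isnan(out["mean_skewness"])

    def test_type7_quantiles(self):
        out = glcm.summarize_tile(self._map_from([1, 2, 3, 4]))
        assert out["entropy_mean"] == 2.5
        assert out["entropy_q1"] == 1.75 and out["entropy_q3"] == 3.25

    def test_symmetric_values_zero_skew(self):
        out = glcm.summarize_tile(self._map_from([-2, -1, 0, 1, 2]))
        assert abs(out["contrast_skewness"]) < 1e-12

    def test_42_features(self):
        out = glcm.summarize_tile(self._map_from([1, 2, 3]))
        assert len(glcm.feature_names()) == 42
        assert set(glcm.feature_names()) <= set(out)

    def test_all_masked_rejected(self):
        tm = self._map_from([1.0])
        tm.valid[:] = False
        with pytest.raises(ValueError):
            glcm.summarize_tile(tm)
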