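import numpy as np
import pytest

import oracles
from nslt.errors import SchemaError, ValidationError
from nslt.texture import (
    FeatureVector,
    aggregate_ns,
    compute_glcm,
    compute_glds,
    compute_glrlm,
    glcm_features,
    glds_features,
    glrlm_features,
    quantize,
)


class TestQuantize:
    def test_uniform_binning_maps_extremes_to_end_levels(self):
        q = quantize(np.array([[0.0, 0.26], [0.51, 1.0]]), 4)
        np.testing.assert_array_equal(q.levels, [[1, 2], [3, 4]])

    def test_constant_image_needs_permission(self):
        img = np.full((3, 3), 0.5)
        with pytest.raises(ValidationError):
            quantize(img, 4)
        assert np.all(quantize(img, 4, allow_constant=True).levels == 1)

    def test_non_constant_image_spans_full_level_range(self, rng):
        q = quantize(rng.random((16, 16)), 8)
        assert q.levels.min() == 1 and q.levels.max() == 8

    def test_too_few_levels_rejected(self, rng):
        with pytest.raises(ValidationError):
            quantize(rng.random((4, 4)), 1)


class TestGLCM:
    def test_horizontal_pair_counts(self, toy_levels_3x3):
        C = compute_glcm(quantize_levels(toy_levels_3x3), (0, 1))
        expected = np.array([[1, 2], [0, 3]]) / 6.0
        np.testing.assert_allclose(C.P, expected)

    def test_constant_image_concentrates_at_diagonal(self):
        q = quantize_levels(np.ones((4, 4), dtype=int))
        C = compute_glcm(q, (0, 1))
        assert C.P[0, 0] == 1.0 and C.P.sum() == pytest.approx(1.0)

    def test_normalization(self, rng):
        q = quantize_levels(rng.integers(1, 6, (9, 9)), 5)
        assert compute_glcm(q, (-1, 1)).P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_worked_feature_values(self, toy_levels_3x3):
        f = glcm_features(compute_glcm(quantize_levels(toy_levels_3x3), (0, 1)))
        assert f["hom"] == pytest.approx(5 / 6)
        assert f["mom1"] == pytest.approx(-1 / 3)
        assert f["mom2"] == pytest.approx(2 / 6)

    def test_one_hot_diagonal_mass(self):
        q = quantize_levels(np.full((3, 3), 2, dtype=int), 3)
        f = glcm_features(compute_glcm(q, (0, 1)))
        assert f["hom"] == 1 and f["enr"] == 1 and f["ent"] == 0
        assert f["con"] == 0 and f["sym"] == 0
        assert all(f[f"mom{k}"] == 0 for k in (1, 2, 3, 4))
        assert "degenerate_correlation" in f.flags and f["cor"] == 0.0

    def test_symmetric_matrix_has_zero_symmetry_feature(self):
        q = quantize_levels(np.array([[1, 2], [2, 1]]), 2)
        f = glcm_features(compute_glcm(q, (0, 1)))
        assert f["sym"] == 0.0

    def test_offset_must_be_nonzero_and_in_bounds(self, toy_levels_3x3):
        q = quantize_levels(toy_levels_3x3)
        with pytest.raises(ValidationError):
            compute_glcm(q, (0, 0))
        with pytest.raises(ValidationError):
            compute_glcm(q, (0, 5))


class TestGLRLM:
    def test_toy_row_runs(self, toy_row):
        R = compute_glrlm(quantize_levels(toy_row, 3), 0)
        assert R.n_runs == 3 and R.n_pixels == 6
        assert R.P[0, 1] == 1 and R.P[1, 2] == 1 and R.P[2, 0] == 1

    def test_toy_row_features(self, toy_row):
        f = glrlm_features(compute_glrlm(quantize_levels(toy_row, 3), 0))
        assert f["sre"] == pytest.approx((1 / 4 + 1 / 9 + 1) / 3)
        assert f["lre"] == pytest.approx(14 / 3)
        assert f["gln"] == pytest.approx(1.0)
        assert f["rln"] == pytest.approx(1.0)
        assert f["rp"] == pytest.approx(0.5)
        assert f["lgre"] == pytest.approx((1 + 1 / 4 + 1 / 9) / 3)
        assert f["hgre"] == pytest.approx(14 / 3)

    def test_single_pixel_image(self):
        f = glrlm_features(compute_glrlm(quantize_levels(np.array([[1]]), 2), 0))
        for name in ("sre", "lre", "rp", "gln", "rln"):
            assert f[name] == 1.0

    def test_constant_row_scalings(self):
        n = 7
        f = glrlm_features(compute_glrlm(quantize_levels(np.ones((1, n), dtype=int), 2), 0))
        assert f["rp"] == pytest.approx(1 / n)
        assert f["sre"] == pytest.approx(1 / n**2)
        assert f["lre"] == pytest.approx(n**2)

    def test_checkerboard_has_all_unit_runs(self):
        board = 1 + (np.indices((6, 6)).sum(axis=0) % 2)
        R = compute_glrlm(quantize_levels(board, 2), 0)
        assert R.n_runs == R.n_pixels

    @pytest.mark.parametrize("direction", [45, 135])
    def test_diagonal_directions_count_every_pixel_once(self, rng, direction):
        q = quantize_levels(rng.integers(1, 4, (5, 8)), 3)
        R = compute_glrlm(q, direction)
        assert (R.P * np.arange(1, R.P.shape[1] + 1)).sum() == q.levels.size


class TestGLDS:
    def test_constant_image_is_point_mass_at_zero(self):
        H = compute_glds(quantize_levels(np.ones((4, 4), dtype=int), 2), (0, 1))
        assert H.P[0] == 1.0

    def test_checkerboard_horizontal_differences(self):
        board = 1 + (np.indices((4, 4)).sum(axis=0) % 2)
        H = compute_glds(quantize_levels(board, 2), (0, 1))
        assert H.P[1] == 1.0
        f = glds_features(H)
        assert (f["asm"], f["con"], f["men"], f["ent"]) == (1.0, 1.0, 1.0, 0.0)

    def test_alternating_row_with_gap_two(self):
        H = compute_glds(quantize_levels(np.array([[1, 3, 1, 3]]), 3), (0, 1))
        assert H.P[2] == 1.0

    def test_half_half_histogram_features(self):
        H = compute_glds(quantize_levels(np.array([[1, 1, 3, 1]]), 3), (0, 1))
        np.testing.assert_allclose(H.P, [1 / 3, 0, 2 / 3])
        f = glds_features(H)
        assert f["con"] == pytest.approx(8 / 3)
        assert f["men"] == pytest.approx(4 / 3)


class TestBruteForceOracle:
    """Vectorized features must match nested-loop evaluation of the printed
    formulas on random small quantized images."""

    @pytest.mark.parametrize("trial", range(20))
    def test_glcm_matches_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        lv = rng.integers(1, 6, (8, 8))
        q = quantize_levels(lv, 5)
        offset = [(0, 1), (-1, 1), (-1, 0), (-1, -1)][trial % 4]
        ours = glcm_features(compute_glcm(q, offset))
        ref = oracles.glcm_features(oracles.glcm_counts(lv.tolist(), 5, *offset))
        for k, v in ref.items():
            assert ours[k] == pytest.approx(v, abs=1e-10), k

    @pytest.mark.parametrize("trial", range(20))
    def test_glrlm_matches_oracle(self, trial):
        rng = np.random.default_rng(2000 + trial)
        lv = rng.integers(1, 5, (8, 8))
        q = quantize_levels(lv, 4)
        direction = [0, 45, 90, 135][trial % 4]
        ours = glrlm_features(compute_glrlm(q, direction))
        runs = oracles.glrlm_runs(lv.tolist(), direction)
        ref = oracles.glrlm_features(runs, lv.size)
        for k, v in ref.items():
            assert ours[k] == pytest.approx(v, abs=1e-10), k

    @pytest.mark.parametrize("trial", range(20))
    def test_glds_matches_oracle(self, trial):
        rng = np.random.default_rng(3000 + trial)
        lv = rng.integers(1, 7, (8, 8))
        q = quantize_levels(lv, 6)
        d = [(1, 1), (0, 1), (1, 0), (1, -1)][trial % 4]
        ours = glds_features(compute_glds(q, d))
        ref = oracles.glds_features(oracles.glds_histogram(lv.tolist(), 6, *d))
        for k, v in ref.items():
            assert ours[k] == pytest.approx(v, abs=1e-10), k

    def test_glcm_matches_skimage_counts(self, rng):
        """Independent library cross-check of the raw co-occurrence counts."""
        from skimage.feature import graycomatrix

        lv = rng.integers(1, 9, (16, 16))
        q = quantize_levels(lv, 8)
        ours = compute_glcm(q, (0, 1)).P
        ref = graycomatrix(lv.astype(np.uint8), [1], [0], levels=9, normed=True)
        np.testing.assert_allclose(ours, ref[1:, 1:, 0, 0], atol=1e-12)


class TestAggregation:
    def test_sum_identity(self):
        fT = FeatureVector({"a": 1.0, "b": 2.0})
        zero = FeatureVector({"a": 0.0, "b": 0.0})
        assert aggregate_ns(fT, zero, zero) == fT

    def test_commutative(self):
        f1 = FeatureVector({"x": 1.0})
        f2 = FeatureVector({"x": 10.0})
        f3 = FeatureVector({"x": 100.0})
        assert aggregate_ns(f1, f2, f3) == aggregate_ns(f3, f1, f2)

    def test_one_hot_homogeneity_sums_to_three(self):
        q = quantize_levels(np.full((3, 3), 1, dtype=int), 2)
        f = glcm_features(compute_glcm(q, (0, 1)))
        assert aggregate_ns(f, f, f)["hom"] == pytest.approx(3.0)

    def test_mismatched_names_rejected(self):
        with pytest.raises(SchemaError):
            aggregate_ns(FeatureVector({"a": 1.0}), FeatureVector({"b": 1.0}),
                         FeatureVector({"a": 1.0}))


class TestInvariants:
    def test_translation_invariance_of_pair_counts(self, rng):
        """Tiling the image preserves per-direction pair statistics."""
        lv = rng.integers(1, 5, (6, 6))
        doubled = np.tile(lv, (1, 2))
        f1 = glds_features(compute_glds(quantize_levels(lv, 4), (1, 0)))
        f2 = glds_features(compute_glds(quantize_levels(doubled, 4), (1, 0)))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)

    def test_feature_ranges(self, rng):
        q = quantize_levels(rng.integers(1, 9, (12, 12)), 8)
        f = glcm_features(compute_glcm(q, (0, 1)))
        assert 0 < f["enr"] <= 1 and 0 < f["hom"] <= 1 and f["ent"] >= 0
        g = glrlm_features(compute_glrlm(q, 0))
        assert g["sre"] <= 1.0 + 1e-12 and 0 < g["rp"] <= 1


def quantize_levels(levels, n_levels=None):
    """Wrap an integer level array as a QuantizedImage."""
    from nslt.texture import QuantizedImage

    lv = np.asarray(levels, dtype=np.int64)
    return QuantizedImage(lv, int(n_levels or max(2, lv.max())))
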