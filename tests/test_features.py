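import numpy as np
import pandas as pd
import pytest

from pannet_radiomics import (
    FEATURE_NAMES,
    Glcm,
    LesionMask,
    SuvVolume,
    compute_glcm,
    extract_feature_vector,
    first_order_features,
    make_glcm_fixture,
    normalize_features,
    quantize,
    second_order_features,
)
from pannet_radiomics.features import apply_normalization, glcm_counts

from oracles import glcm_counts_bruteforce, second_order_direct, skewness_kurtosis_textbook


def full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return LesionMask(np.ones(shape, bool), spacing)


class TestQuantize:
    def test_constant_lesion_all_level_one(self):
        vol = SuvVolume(np.full((5, 5, 5), 3.0), (1, 1, 1))
        q = quantize(vol, full_mask((5, 5, 5)))
        assert (q.levels[q.mask] == 1).all()

    def test_linear_ramp_spans_all_levels_once(self):
        vals = np.arange(64, dtype=float).reshape(64, 1, 1)
        vol = SuvVolume(vals, (1, 1, 1))
        q = quantize(vol, full_mask((64, 1, 1)), n_levels=64)
        levels = np.sort(q.levels[q.mask])
        # closed form: floor((v - 0)/63 * 64) + 1 clamps the top value to 64
        expected = np.minimum(np.floor(np.arange(64) / 63 * 64).astype(int) + 1, 64)
        assert (levels == np.sort(expected)).all()
        assert levels.min() == 1 and levels.max() == 64

    def test_max_value_clamps_to_top_level(self):
        vals = np.array([0.0, 1.0, 2.0]).reshape(3, 1, 1)
        q = quantize(SuvVolume(vals, (1, 1, 1)), full_mask((3, 1, 1)), n_levels=64)
        assert q.levels[2, 0, 0] == 64


class TestGlcm:
    def test_constant_slice_all_mass_on_1_1(self):
        q = make_glcm_fixture("constant", (4, 4))
        g = compute_glcm(q, 1)
        assert g.matrix[0, 0] == pytest.approx(1.0)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_checkerboard_horizontal_pairs(self):
        q = make_glcm_fixture("checkerboard", (4, 4))
        g = compute_glcm(q, 1, angles=(0.0,))  # horizontal offsets only
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)
        assert g.matrix[0, 0] == pytest.approx(0.0)

    @pytest.mark.parametrize("d", [1, 2, 3, 4])
    def test_random_fixture_matches_bruteforce_counts(self, d):
        q = make_glcm_fixture("random", (8, 8), seed=42)
        counts = glcm_counts(q, d)
        oracle = glcm_counts_bruteforce(q.levels, q.mask, d)
        assert (counts == oracle).all()

    def test_phantom_matches_bruteforce_counts(self, phantom):
        vol, mask = phantom
        q = quantize(vol, mask)
        counts = glcm_counts(q, 2)
        oracle = glcm_counts_bruteforce(q.levels, q.mask, 2)
        assert (counts == oracle).all()

    def test_matrix_symmetric_and_normalized(self, phantom):
        vol, mask = phantom
        q = quantize(vol, mask)
        for d in (1, 2, 3, 4):
            g = compute_glcm(q, d)
            assert np.allclose(g.matrix, g.matrix.T)
            assert g.matrix.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_valid_pair_raises(self):
        q = make_glcm_fixture("random", (2, 2), seed=0)
        with pytest.raises(ValueError, match="distance"):
            compute_glcm(q, 5)


class TestFirstOrder:
    def test_constant_lesion(self):
        vol = SuvVolume(np.full((5, 5, 5), 5.0), (1, 1, 1))
        f = first_order_features(vol, full_mask((5, 5, 5)))
        assert f["mean_SUV"] == 5.0
        assert f["variance_SUV"] == 0.0
        assert f["E_SUV"] == 0.0
        assert f["uniformity_SUV"] == 1.0
        assert f["skewness_SUV"] == 0.0
        assert f["kurtosis_SUV"] == 0.0

    def test_uniform_ramp_entropy_six_bits(self):
        vals = (np.arange(64, dtype=float) + 0.5).reshape(64, 1, 1)
        f = first_order_features(SuvVolume(vals, (1, 1, 1)), full_mask((64, 1, 1)))
        assert f["E_SUV"] == pytest.approx(6.0)

    def test_skewness_kurtosis_match_textbook_formula(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            vals = rng.gamma(2.0, 1.0, size=int(rng.integers(10, 80)))
            vol = SuvVolume(vals.reshape(-1, 1, 1), (1, 1, 1))
            f = first_order_features(vol, full_mask(vol.shape))
            skew, kurt = skewness_kurtosis_textbook(vals)
            assert f["skewness_SUV"] == pytest.approx(skew, rel=1e-9)
            assert f["kurtosis_SUV"] == pytest.approx(kurt, rel=1e-9)


class TestSecondOrder:
    def test_diagonal_concentration_closed_forms(self):
        m = np.zeros((64, 64))
        m[0, 0] = 1.0
        f = second_order_features(Glcm(m, 1))
        assert f["E_GLCM-1"] == 0.0
        assert f["NH_GLCM-1"] == pytest.approx(1.0)
        assert f["contrast_GLCM-1"] == 0.0
        assert f["energy_GLCM-1"] == 1.0

    def test_uniform_over_k_cells_entropy_log2k(self):
        for k in (2, 4, 8):
            m = np.zeros((8, 8))
            for i in range(k):
                m[i, i] = 1.0 / k
            f = second_order_features(Glcm(m, 1))
            assert f["E_GLCM-1"] == pytest.approx(np.log2(k))

    def test_all_features_match_direct_summation(self):
        q = make_glcm_fixture("random", (8, 8), seed=7)
        g = compute_glcm(q, 1)
        f = second_order_features(g)
        oracle = second_order_direct(g.matrix)
        for name, val in oracle.items():
            assert f[f"{name}_GLCM-1"] == pytest.approx(val, rel=1e-9), name

    def test_entropy_permutation_invariant_contrast_not(self):
        q = make_glcm_fixture("random", (8, 8), seed=3)
        g = compute_glcm(q, 1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.matrix.shape[0])
        permuted = Glcm(g.matrix[np.ix_(perm, perm)], 1)
        f0, f1 = second_order_features(g), second_order_features(permuted)
        assert f0["E_GLCM-1"] == pytest.approx(f1["E_GLCM-1"])
        assert f0["contrast_GLCM-1"] != pytest.approx(f1["contrast_GLCM-1"])

    def test_nh_in_unit_interval_equals_one_iff_diagonal(self, phantom):
        vol, mask = phantom
        q = quantize(vol, mask)
        f = second_order_features(compute_glcm(q, 1))
        assert 0.0 < f["NH_GLCM-1"] < 1.0

    def test_unnormalized_matrix_rejected(self):
        m = np.zeros((4, 4))
        m[0, 0] = 2.0
        with pytest.raises(ValueError):
            Glcm(m, 1)


class TestFeatureVector:
    def test_exactly_sixty_unique_finite_features(self, phantom):
        vol, mask = phantom
        vec = extract_feature_vector(vol, mask)
        assert len(vec) == 60
        assert len(FEATURE_NAMES) == 60
        assert list(vec) == list(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in vec.values())

    def test_identical_lesions_identical_vectors(self, phantom):
        vol, mask = phantom
        assert extract_feature_vector(vol, mask) == extract_feature_vector(vol, mask)

    def test_background_voxels_never_influence_features(self, phantom):
        vol, mask = phantom
        vec0 = extract_feature_vector(vol, mask)
        altered = vol.values.copy()
        altered[~mask.values] = 99.0
        vec1 = extract_feature_vector(SuvVolume(altered, vol.spacing), mask)
        assert vec0 == vec1

    def test_ineligible_mask_rejected(self):
        vol = SuvVolume(np.ones((3, 3, 3)), (1, 1, 1))
        with pytest.raises(ValueError, match="eligible"):
            extract_feature_vector(vol, full_mask((3, 3, 3)))

    def test_adjacent_distance_features_strongly_correlated(self, cohort_features):
        """Second-order features at neighbouring distances are near-collinear
        across a cohort (the reason the selection stage deduplicates them)."""
        hs = cohort_features[cohort_features["source"] == "HS"]
        assert np.corrcoef(hs["E_GLCM-3"], hs["E_GLCM-4"])[0, 1] > 0.8
        assert np.corrcoef(hs["NH_GLCM-3"], hs["NH_GLCM-4"])[0, 1] > 0.8


class TestNormalization:
    def test_training_rows_scaled_to_unit_interval(self, cohort_features):
        hs_rows = cohort_features.index[cohort_features["source"] == "HS"]
        normed, params = normalize_features(cohort_features, hs_rows)
        sub = normed.loc[hs_rows, list(FEATURE_NAMES)]
        assert np.allclose(sub.min(axis=0), 0.0)
        assert np.allclose(sub.max(axis=0), 1.0)
        # test rows may leave [0, 1]
        other = normed.drop(index=hs_rows)[list(FEATURE_NAMES)]
        assert (other.values < 0).any() or (other.values > 1).any()

    def test_reapplying_stored_params_reproduces_values(self, cohort_features):
        hs_rows = cohort_features.index[cohort_features["source"] == "HS"]
        normed, params = normalize_features(cohort_features, hs_rows)
        again = apply_normalization(cohort_features[list(FEATURE_NAMES)], params)
        assert np.allclose(again.values, normed[list(FEATURE_NAMES)].values)

    def test_zero_range_feature_maps_to_zero(self):
        table = pd.DataFrame({"grade": ["G1", "G2", "G1"], "NH_GLCM-1": [1.0, 1.0, 1.0],
                              "E_SUV": [1.0, 2.0, 3.0]})
        normed, params = normalize_features(table, table.index,
                                            feature_cols=["NH_GLCM-1", "E_SUV"])
        assert (normed["NH_GLCM-1"] == 0).all()
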