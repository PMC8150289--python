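import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pannet_radiomics.stats import (
    confusion_metrics,
    holm_bonferroni,
    icc,
    pearson_corr,
    roc_auc,
    wilcoxon_rank_sum,
    youden_cutoff,
)

from oracles import auc_paircount, icc_a1_hand, wilcoxon_exact_enumeration


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 1.1, 1.2, 1.3])
        labels = np.array(["G1"] * 3 + ["G2"] * 3)
        roc = roc_auc(scores, labels, n_boot=100)
        assert roc.auc == 1.0
        assert roc.youden_index == 1.0
        # returned cutoff is the midpoint between the two classes
        assert 0.3 < roc.youden_cutoff < 1.1
        assert roc.youden_cutoff == pytest.approx(0.7)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = rng.choice(np.round(rng.normal(size=8), 1), size=n)  # induce ties
            labels = rng.choice(["G1", "G2"], size=n)
            if len(set(labels)) < 2:
                continue
            roc = roc_auc(scores, labels, n_boot=0)
            assert roc.auc == pytest.approx(auc_paircount(scores, labels, "G2"), abs=1e-12)

    def test_complement_identity_for_tie_free_scores(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=20)
        labels = rng.choice(["G1", "G2"], size=20)
        labels[:2] = "G1"
        labels[-2:] = "G2"
        a = roc_auc(scores, labels, n_boot=0).auc
        b = roc_auc(-scores, labels, n_boot=0).auc
        assert a + b == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, "G1", "G2")
        assert roc_auc(scores, labels, n_boot=0).auc == pytest.approx(0.5, abs=0.05)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(0, 1, 15), rng.normal(1, 1, 15)])
        labels = np.array(["G1"] * 15 + ["G2"] * 15)
        roc = roc_auc(scores, labels, n_boot=500, seed=4)
        assert roc.ci[0] <= roc.auc <= roc.ci[1]

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], ["G1", "G1", "G1"])


class TestYouden:
    def test_sensitivity_92_specificity_85_gives_yi_077(self):
        # informedness from the printed optimum: 0.92 + 0.85 - 1
        assert 0.92 + 0.85 - 1 == pytest.approx(0.77)

    def test_counts_11_of_12_and_11_of_13_give_informedness_076(self):
        cm = confusion_metrics(tp=11, fp=2, tn=11, fn=1)
        assert round(cm.informedness, 2) == 0.76

    def test_cutoff_maximizes_informedness(self):
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(0, 1, 12), rng.normal(1.5, 1, 13)])
        labels = np.array(["G1"] * 12 + ["G2"] * 13)
        roc = roc_auc(scores, labels, n_boot=0)
        cutoff, yi = youden_cutoff(roc)
        calls = scores >= cutoff
        pos = labels == "G2"
        sens = (calls & pos).sum() / pos.sum()
        spec = (~calls & ~pos).sum() / (~pos).sum()
        assert sens + spec - 1 == pytest.approx(yi)
        # no threshold does better
        for t in np.unique(scores):
            c = scores >= t
            s1 = (c & pos).sum() / pos.sum()
            s2 = (~c & ~pos).sum() / (~pos).sum()
            assert s1 + s2 - 1 <= yi + 1e-12


class TestConfusionMetrics:
    def test_histology_training_worked_example(self):
        # 11/12 G2 detected, 11/13 G1 correct
        cm = confusion_metrics(tp=11, fp=2, tn=11, fn=1)
        assert round(100 * cm.sensitivity) == 92
        assert round(100 * cm.specificity) == 85
        assert round(100 * cm.ppv) == 85
        assert round(100 * cm.npv) == 92
        assert round(cm.informedness, 2) == 0.76
        assert round(cm.fdr, 2) == 0.15

    def test_suvmax_worked_example(self):
        # 5/12 G2 detected with 2 false positives
        cm = confusion_metrics(tp=5, fn=7, tn=11, fp=2)
        assert round(100 * cm.ppv) == 71
        assert round(100 * cm.npv) == 61
        assert round(100 * cm.accuracy) == 64

    def test_transfer_validation_worked_example(self):
        # 7/8 G2 detected on the biopsy cohort with 3 false positives
        cm = confusion_metrics(tp=7, fn=1, tn=15, fp=3)
        assert round(100 * cm.sensitivity) == 88
        assert round(100 * cm.specificity) == 83
        assert round(100 * cm.ppv) == 70
        assert round(100 * cm.npv) == 94
        assert round(100 * cm.accuracy) == 85
        assert round(cm.informedness, 2) == 0.71

    def test_all_correct(self):
        cm = confusion_metrics(tp=10, fp=0, tn=10, fn=0)
        for v in (cm.sensitivity, cm.specificity, cm.ppv, cm.npv, cm.accuracy):
            assert v == 1.0
        assert cm.fdr == 0.0

    def test_undefined_ratio_is_nan_not_zero(self):
        cm = confusion_metrics(tp=0, fp=0, tn=5, fn=5)
        assert np.isnan(cm.ppv)
        assert np.isnan(cm.fdr)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(tp=-1, fp=0, tn=0, fn=0)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert wilcoxon_rank_sum(x, x) == 1.0

    def test_matches_exact_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                wilcoxon_exact_enumeration(x, y), abs=1e-12)

    def test_fully_separated_12_vs_13(self):
        import math

        x = np.arange(13) + 100.0
        y = np.arange(12.0)
        # exact minimal two-sided p for complete separation
        assert wilcoxon_rank_sum(x, y) == pytest.approx(2.0 / math.comb(25, 12), rel=1e-9)

    def test_matches_scipy_exact_branch(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(3, 12)))
            y = rng.normal(size=int(rng.integers(3, 12)))
            expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert wilcoxon_rank_sum(x, y) == pytest.approx(expected, rel=1e-9)

    def test_matches_scipy_asymptotic_branch_with_ties(self):
        rng = np.random.default_rng(10)
        x = np.round(rng.normal(size=20), 1)
        y = np.round(rng.normal(0.5, 1, size=18), 1)
        expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(expected, rel=1e-9)

    def test_exact_vs_approximation_agree_at_n10(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        y = rng.normal(0.8, 1, size=10)
        exact = wilcoxon_rank_sum(x, y)
        approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert exact == pytest.approx(approx, abs=0.01)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(0.5, 1, size=9)
        p1 = wilcoxon_rank_sum(x, y)
        p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestHolm:
    def test_single_p_unchanged(self):
        reject, adj = holm_bonferroni([0.03])
        assert reject[0]
        assert adj[0] == pytest.approx(0.03)

    def test_hand_stepdown_example(self):
        reject, adj = holm_bonferroni([0.01, 0.02, 0.05], alpha=0.05)
        assert reject.all()
        assert adj == pytest.approx([0.03, 0.04, 0.05])

    def test_all_ones(self):
        reject, adj = holm_bonferroni([1.0, 1.0, 1.0])
        assert not reject.any()
        assert (adj == 1.0).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(10):
            p = rng.random(int(rng.integers(1, 40)))
            reject, adj = holm_bonferroni(p, alpha=0.05)
            sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.05, method="holm")
            assert np.allclose(adj, sm_adj)
            assert (reject == sm_rej).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_uniformly_more_powerful_than_bonferroni(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(12)
        reject, _ = holm_bonferroni(p, alpha=0.05)
        bonferroni = p <= 0.05 / p.size
        assert (reject | ~bonferroni).all()  # every Bonferroni rejection is a Holm rejection


class TestPearsonAndIcc:
    def test_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_corr(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert pearson_corr(x, y) == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(pearson_corr(np.ones(5), np.arange(5.0)))

    def test_icc_identical_measurements(self):
        vals = np.array([1.0, 2.0, 5.0, 9.0])
        assert icc(vals, vals) == pytest.approx(1.0)

    def test_icc_independent_noise_near_zero(self):
        rng = np.random.default_rng(12)
        vals = [icc(rng.normal(size=40), rng.normal(size=40)) for _ in range(50)]
        assert abs(np.mean(vals)) < 0.1

    def test_icc_matches_hand_anova_on_toy_table(self):
        a = np.array([9.0, 6.0, 8.0, 7.0])
        b = np.array([8.0, 5.0, 9.0, 6.0])
        assert icc(a, b) == pytest.approx(icc_a1_hand(a, b), abs=1e-12)

    def test_icc_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(13)
        a = rng.normal(size=12)
        b = a + rng.normal(0, 0.3, size=12)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["o", "p"], 12),
            "score": np.column_stack([a, b]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])  # label differs across versions
        icc_a1 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc(a, b) == pytest.approx(icc_a1, abs=1e-9)

    def test_icc_needs_three_subjects(self):
        with pytest.raises(ValueError):
            icc([1.0, 2.0], [1.0, 2.0])
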