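"""Statistical primitives used throughout the grading pipeline.

ROC/AUC with bootstrap confidence intervals, the Youden index, confusion
metrics, the two-tailed Wilcoxon rank-sum test, Holm-Bonferroni step-down
correction, Pearson correlation and the intraclass correlation coefficient.

The rank-sum test keeps an exact null distribution (dynamic programme, cached
per sample-size pair) for tie-free samples of combined size <= 25 — the cohort
sizes this pipeline screens thousands of feature pairs at — and falls back to
the tie-corrected normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "RocResult",
    "ConfusionMetrics",
    "roc_auc",
    "youden_cutoff",
    "confusion_metrics",
    "wilcoxon_rank_sum",
    "holm_bonferroni",
    "pearson_corr",
    "icc",
]


# ---------------------------------------------------------------------------
# ROC / AUC / Youden


@dataclass
class RocResult:
    """Empirical ROC curve of a score against a binary label.

    ``thresholds`` are candidate cutoffs (midpoints between consecutive
    distinct scores plus sentinels); a case is called positive when its score
    is >= the cutoff. ``auc`` equals the Mann-Whitney statistic U/(n1*n2) with
    ties counted 1/2; ``ci`` is a stratified-bootstrap 95% interval.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci: tuple[float, float]
    youden_cutoff: float
    youden_index: float


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def _curve(scores: np.ndarray, positive: np.ndarray, thresholds: np.ndarray):
    calls = scores[None, :] >= thresholds[:, None]
    tp = (calls & positive[None, :]).sum(axis=1)
    fp = (calls & ~positive[None, :]).sum(axis=1)
    tpr = tp / positive.sum()
    fpr = fp / (~positive).sum()
    return tpr, fpr


def _mw_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2, via midranks."""
    n1, n0 = pos_scores.size, neg_scores.size
    ranks = sps.rankdata(np.concatenate([pos_scores, neg_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores, labels, positive="G2", n_boot: int = 2000, seed: int = 0) -> RocResult:
    """Empirical ROC, trapezoid AUC and a stratified-bootstrap 95% CI.

    ``labels`` may be any array; cases equal to ``positive`` are the positive
    class (by default the higher tumour grade G2).
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute a ROC curve")

    auc = float(roc_auc_score(pos.astype(int), scores))
    thresholds = _candidate_thresholds(scores)
    tpr, fpr = _curve(scores, pos, thresholds)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pos_scores, neg_scores = scores[pos], scores[~pos]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = _mw_auc(
                rng.choice(pos_scores, n1, replace=True),
                rng.choice(neg_scores, n0, replace=True),
            )
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (float("nan"), float("nan"))

    cutoff, yi = _youden_from_curve(thresholds, tpr, fpr)
    return RocResult(thresholds, tpr, fpr, auc, ci, cutoff, yi)


def _youden_from_curve(thresholds, tpr, fpr) -> tuple[float, float]:
    yi = tpr - fpr
    best = yi.max()
    # ties broken toward higher specificity (lower FPR), then higher cutoff
    cand = np.flatnonzero(np.isclose(yi, best))
    cand = cand[fpr[cand] == fpr[cand].min()]
    idx = cand[np.argmax(thresholds[cand])]
    return float(thresholds[idx]), float(best)


def youden_cutoff(roc: RocResult) -> tuple[float, float]:
    """The cutoff maximizing sensitivity + specificity - 1, and that maximum."""
    return _youden_from_curve(roc.thresholds, roc.tpr, roc.fpr)


# ---------------------------------------------------------------------------
# Confusion metrics


def _ratio(num: float, den: float) -> float:
    """A proportion that is NaN (undefined), not zero, on an empty margin."""
    return num / den if den > 0 else float("nan")


@dataclass
class ConfusionMetrics:
    """Derived classification metrics, recomputed from the four counts on access."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return _ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def informedness(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def fdr(self) -> float:
        return _ratio(self.fp, self.tp + self.fp)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "informedness": self.informedness, "fdr": self.fdr,
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@functools.lru_cache(maxsize=64)
def _exact_u_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under the tie-free null.

    Counts subsets of size ``n1`` from ranks 1..n1+n2 by rank-sum via dynamic
    programming, then converts to U = ranksum - n1(n1+1)/2.
    """
    n = n1 + n2
    max_sum = n1 * n + 1  # rank sums are at most n1*n
    table = np.zeros((n1 + 1, max_sum), dtype=float)
    table[0, 0] = 1.0
    for value in range(1, n + 1):
        for k in range(min(value, n1), 0, -1):
            table[k, value:] += table[k - 1, :max_sum - value]
    counts = table[n1, n1 * (n1 + 1) // 2: n1 * (n1 + 1) // 2 + n1 * n2 + 1]
    return np.cumsum(counts) / math.comb(n, n1)


def wilcoxon_rank_sum(x, y, two_tailed: bool = True) -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for tie-free samples with combined n <= 25; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 + n2 <= 25:
        cdf = _exact_u_cdf(n1, n2)
        u_min = int(round(min(u1, u2)))
        p = 2.0 * cdf[u_min]
    else:
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return 1.0
        z = (max(u1, u2) - mu - 0.5) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(z)
    if not two_tailed:
        p /= 2.0
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Multiple testing, correlation, ICC


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down correction.

    Returns (reject flags, adjusted p-values); adjusted p_i is the running
    maximum of (m - rank) * p over the step-down chain, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj <= alpha, adj


def pearson_corr(x, y) -> float:
    """Product-moment correlation; NaN (with a warning) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_corr needs two equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: Pearson correlation undefined", RuntimeWarning)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def icc(original_values, perturbed_values) -> float:
    """ICC(A,1): two-way mixed effects, absolute agreement, single measurement.

    Computed from the ANOVA mean squares of the n-subjects x 2-measurements
    table (McGraw-Wong form). Identical measurements give 1; NaN when the
    table has no subject variance at all.
    """
    a = np.asarray(original_values, dtype=float)
    b = np.asarray(perturbed_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("icc expects two equal-length 1D arrays")
    n = a.size
    if n < 3:
        raise ValueError("icc needs paired measurements on at least 3 subjects")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)
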