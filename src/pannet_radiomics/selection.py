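"""Feature selection: correlation pre-filter, single and pair screening, LDA signatures.

The selection stage mirrors the training of the histology-anchored model:
on the training cohort it (1) deduplicates near-collinear single features and
enumerates the C(60,2) = 1770 unordered feature couples, keeping only couples
with low mutual correlation; (2) screens each surviving candidate by the
two-tailed Wilcoxon rank-sum p of its G2/G1 separation (on the raw feature
for singles, on the LDA radiomic score for couples) under Holm correction —
singles and couples corrected as separate families; and (3) ranks survivors
by (p ascending, AUC descending) to pick the winners.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .features import FEATURE_NAMES, normalize_features
from .models import RadiomicLDA, RadiomicSignature, _fast_auc, _fit_signature
from .stats import holm_bonferroni, roc_auc, wilcoxon_rank_sum, youden_cutoff

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "correlation_prefilter",
    "evaluate_single",
    "lda_signature",
    "select",
    "PairSignatureSelector",
]

# feature families by texture axis: the local grey-level-difference axis
# (inverse-difference and difference-moment features) and the
# disorder/orderliness axis (entropy and its monotone duals: angular second
# moment / uniformity / maximum probability). First-order energy (sum of
# squared SUV) is an intensity-magnitude feature and belongs to neither.
HOMOGENEITY_FAMILY = ("NH", "homogeneity", "contrast", "dissimilarity")
ENTROPY_FAMILY = ("E", "uniformity", "max_prob")


@dataclass
class SelectionResult:
    """Ranked screening tables and the winning single feature / feature pair."""

    singles: pd.DataFrame
    pairs: pd.DataFrame
    winner_single: str | None
    winner_pair: tuple[str, str] | None
    n_candidate_pairs_total: int
    n_candidate_pairs_kept: int
    thresholds: dict = field(default_factory=dict)


def correlation_prefilter(
    table: pd.DataFrame,
    feature_cols=None,
    single_thresh: float = 0.90,
    pair_thresh: float = 0.30,
    labels=None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Greedy single-feature deduplication and low-mutual-correlation pair candidates.

    Singles: walking the features in their fixed registry order, a feature is
    dropped when its |Pearson rho| with an already-kept feature is >=
    ``single_thresh``. Couples are then formed from the deduplicated singles
    and kept when their mutual |rho| is <= ``pair_thresh``, so the surviving
    couples are not redundant re-pairings of near-collinear features and the
    multiple-testing family stays small enough for a moderately separating
    couple to survive the Holm screen.

    When ``labels`` is given, redundancy is measured by the *within-class*
    correlation (features centred per class before correlating): two features
    that co-vary only because each separates the classes carry complementary,
    not redundant, information and must not be filtered against each other,
    while monotone duals of the same measurement stay correlated within class
    and are pruned.
    """
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_NAMES if c in table.columns]
    if len(table) < 3:
        raise ValueError("correlation prefilter needs at least 3 rows")
    X = table[feature_cols].to_numpy(dtype=float)
    if labels is not None:
        labels = np.asarray(labels)
        X = X.copy()
        for lab in np.unique(labels):
            sel_rows = labels == lab
            X[sel_rows] -= X[sel_rows].mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # zero-variance features correlate with nothing

    kept: list[int] = []
    for idx in range(len(feature_cols)):
        if all(abs(corr[idx, kpt]) < single_thresh for kpt in kept):
            kept.append(idx)
    kept_singles = [feature_cols[i] for i in kept]

    pairs = [
        (feature_cols[a], feature_cols[b])
        for a, b in itertools.combinations(kept, 2)
        if abs(corr[a, b]) <= pair_thresh
    ]
    return kept_singles, pairs


def evaluate_single(values, labels, seed: int = 0) -> tuple[float, float, float, float]:
    """(Wilcoxon p, AUC, Youden index, Youden cutoff) of one feature vs grade.

    The screening path needs no confidence interval, so the ROC is computed
    without the bootstrap.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if np.unique(values).size == 1:
        return 1.0, 0.5, 0.0, float(values[0])
    p = wilcoxon_rank_sum(values[labels == "G2"], values[labels == "G1"])
    roc = roc_auc(values, labels, positive="G2", seed=seed, n_boot=0)
    cutoff, yi = youden_cutoff(roc)
    return p, roc.auc, yi, cutoff


def lda_signature(pair_values, labels, feature_names=("f0", "f1")) -> RadiomicSignature:
    """Fit an equal-prior LDA on per-patient 2-vectors and wrap it as a signature.

    ``pair_values`` are assumed already normalized; the returned signature
    carries identity normalization parameters.
    """
    X = np.asarray(pair_values, dtype=float)
    lda = RadiomicLDA().fit(X, np.asarray(labels))
    norm = {name: (0.0, 1.0) for name in feature_names}
    return RadiomicSignature(list(feature_names), lda.coef_, lda.intercept_, norm)


def _screen_scores(scores: np.ndarray, pos: np.ndarray) -> tuple[float, float]:
    """Fast (Wilcoxon p, AUC) of a score vector against a fixed grade split."""
    p = wilcoxon_rank_sum(scores[pos], scores[~pos])
    grade = np.where(pos, "G2", "G1")
    return p, _fast_auc(scores, grade)


def select(
    table: pd.DataFrame,
    feature_cols=None,
    alpha: float = 0.05,
    single_thresh: float = 0.90,
    pair_thresh: float = 0.30,
    seed: int = 0,
) -> SelectionResult:
    """Full selection pass on one training cohort.

    Features are min-max normalized on the given rows; singles and couples
    surviving the correlation pre-filter are screened by Holm-corrected
    Wilcoxon p (couples screened on their LDA radiomic score) and ranked by
    (p ascending, AUC descending). Returns ranked tables plus the winners;
    an empty result (no survivor) is logged, not an error.
    """
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_NAMES if c in table.columns]
    n_total_pairs = len(feature_cols) * (len(feature_cols) - 1) // 2
    normed, _ = normalize_features(table, table.index, feature_cols=feature_cols)
    labels = table["grade"].to_numpy()
    pos = labels == "G2"
    if pos.all() or not pos.any():
        raise ValueError("both grades must be present in the training cohort")

    kept_singles, candidate_pairs = correlation_prefilter(
        normed, feature_cols, single_thresh=single_thresh, pair_thresh=pair_thresh,
        labels=labels,
    )

    X = normed[feature_cols].to_numpy(dtype=float)
    col_of = {c: k for k, c in enumerate(feature_cols)}

    single_rows = []
    for c in kept_singles:
        p, auc, yi, cutoff = evaluate_single(X[:, col_of[c]], labels, seed=seed)
        single_rows.append({"feature": c, "p": p, "auc": auc, "yi": yi, "cutoff": cutoff})
    singles = pd.DataFrame(single_rows)
    if len(singles):
        _, singles["p_adj"] = holm_bonferroni(singles["p"].to_numpy(), alpha=alpha)

    pair_rows = []
    for a, b in candidate_pairs:
        Xp = X[:, [col_of[a], col_of[b]]]
        try:
            lda = RadiomicLDA().fit(Xp, labels)
        except ValueError:
            continue
        rs = Xp @ lda.coef_ + lda.intercept_
        p, auc = _screen_scores(rs, pos)
        pair_rows.append({"feature_a": a, "feature_b": b, "p": p, "auc": auc,
                          "w_a": lda.coef_[0], "w_b": lda.coef_[1], "intercept": lda.intercept_})
    pairs = pd.DataFrame(pair_rows)
    if len(pairs):
        _, pairs["p_adj"] = holm_bonferroni(pairs["p"].to_numpy(), alpha=alpha)

    winner_single = None
    if len(singles):
        surv = singles[singles["p_adj"] <= alpha].sort_values(
            ["p", "auc"], ascending=[True, False], kind="stable")
        singles = singles.sort_values(["p", "auc"], ascending=[True, False],
                                      kind="stable").reset_index(drop=True)
        if len(surv):
            winner_single = surv.iloc[0]["feature"]

    winner_pair = None
    if len(pairs):
        surv = pairs[pairs["p_adj"] <= alpha].sort_values(
            ["p", "auc"], ascending=[True, False], kind="stable")
        pairs = pairs.sort_values(["p", "auc"], ascending=[True, False],
                                  kind="stable").reset_index(drop=True)
        if len(surv):
            winner_pair = (surv.iloc[0]["feature_a"], surv.iloc[0]["feature_b"])

    if winner_single is None and winner_pair is None:
        logger.info("selection produced no Holm-surviving feature at alpha=%g", alpha)

    return SelectionResult(
        singles=singles,
        pairs=pairs,
        winner_single=winner_single,
        winner_pair=winner_pair,
        n_candidate_pairs_total=n_total_pairs,
        n_candidate_pairs_kept=len(candidate_pairs),
        thresholds={"alpha": alpha, "single_thresh": single_thresh, "pair_thresh": pair_thresh},
    )


def feature_family(name: str) -> str:
    """Coarse texture-axis family of a feature (homogeneity / entropy / other)."""
    base, _, suffix = name.rpartition("_")
    if base in HOMOGENEITY_FAMILY:
        return "homogeneity"
    if base in ENTROPY_FAMILY:
        return "entropy"
    if base == "energy" and suffix.startswith("GLCM"):
        return "entropy"  # angular second moment, the inverse-entropy dual
    return "other"


class PairSignatureSelector(BaseEstimator):
    """sklearn-style wrapper around :func:`select` plus signature fitting.

    ``fit`` runs the full screen on a cohort table and fits the winning
    pair's signature on the same rows; fitted attributes: ``result_``,
    ``winner_pair_``, ``signature_``.
    """

    def __init__(self, alpha: float = 0.05, single_thresh: float = 0.90,
                 pair_thresh: float = 0.30, seed: int = 0):
        self.alpha = alpha
        self.single_thresh = single_thresh
        self.pair_thresh = pair_thresh
        self.seed = seed

    def fit(self, table: pd.DataFrame, y=None):
        self.result_ = select(table, alpha=self.alpha, single_thresh=self.single_thresh,
                              pair_thresh=self.pair_thresh, seed=self.seed)
        self.winner_pair_ = self.result_.winner_pair
        self.signature_ = None
        if self.winner_pair_ is not None:
            self.signature_ = _fit_signature(
                table, self.winner_pair_, table.index,
                provenance={"design": "A", "selection": "winner_pair"})
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if getattr(self, "signature_", None) is None:
            raise ValueError("selector not fitted or no winning pair survived")
        return self.signature_.score(table)[:, None]
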