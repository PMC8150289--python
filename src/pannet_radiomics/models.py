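"""Radiomic signature models and the three training/validation designs.

A radiomic signature is a linear score RS(x) = w.x + b over a small set of
normalized features, fitted by two-class equal-prior linear discriminant
analysis: w = S_pooled^-1 (mu_G2 - mu_G1), b = -w.(mu_G1 + mu_G2)/2. The
decision boundary is RS = 0; RS > 0 calls G2. The three designs are:

* model A — train on histology-graded (HS) patients, validate on biopsy (BS);
* model B — the reverse;
* model C — 100x repeated stratified 3-fold cross-validation on the pooled
  cohort, discarding overfitting runs (validation AUC > training AUC),
  selecting a per-repetition winner by validation AUC, and averaging the
  winners' coefficients into a final signature.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import apply_normalization, normalize_features
from .stats import confusion_metrics, roc_auc, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "RadiomicLDA",
    "RadiomicSignature",
    "CvRunRecord",
    "CvSummary",
    "train_eval_transfer",
    "stratified_folds",
    "repeated_cv",
    "predict",
    "evaluate_signature",
]


class RadiomicLDA(BaseEstimator, ClassifierMixin):
    """Two-class equal-prior LDA in closed form.

    Fisher direction w = S_pooled^-1 (mu_pos - mu_neg) with the boundary at
    the midpoint of the class means; if the pooled covariance is singular a
    ridge ``ridge * I`` is added. ``decision_function`` is the radiomic score
    RS; ``predict`` calls the positive class when RS >= 0 (an exact RS = 0 is
    logged as a boundary case and called positive — conservative toward
    detecting the higher grade).
    """

    def __init__(self, positive_label="G2", ridge: float = 1e-6):
        self.positive_label = positive_label
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_samples, n_features)")
        pos = y == self.positive_label
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos < 2 or n_neg < 2:
            raise ValueError("need at least 2 patients per grade to fit an LDA")
        mu_pos = X[pos].mean(axis=0)
        mu_neg = X[~pos].mean(axis=0)
        resid = np.vstack([X[pos] - mu_pos, X[~pos] - mu_neg])
        cov = resid.T @ resid / (len(X) - 2)
        try:
            w = np.linalg.solve(cov, mu_pos - mu_neg)
        except np.linalg.LinAlgError:
            w = np.linalg.solve(cov + self.ridge * np.eye(cov.shape[0]), mu_pos - mu_neg)
        self.coef_ = w
        self.intercept_ = float(-w @ (mu_pos + mu_neg) / 2.0)
        self.classes_ = np.unique(y)
        negatives = np.unique(y[~pos])
        if negatives.size != 1:
            raise ValueError("exactly one negative class label expected")
        self._negative_label = negatives[0]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        rs = self.decision_function(X)
        if np.any(rs == 0):
            logger.warning("radiomic score exactly 0 for %d case(s); called %s",
                           int((rs == 0).sum()), self.positive_label)
        return np.where(rs >= 0, self.positive_label, self._negative_label)


@dataclass
class RadiomicSignature:
    """A fitted linear radiomic signature with its normalization parameters.

    ``normalization`` maps each feature name to the (min, max) fitted on the
    training rows, so the signature can be deployed on new data exactly as
    trained. ``provenance`` records the design (A/B/C) and training rows.
    """

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    normalization: dict[str, tuple[float, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_names) != self.weights.size:
            raise ValueError("one weight per feature required")

    def score(self, table: pd.DataFrame) -> np.ndarray:
        """Per-patient radiomic score RS on raw (unnormalized) feature rows."""
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise KeyError(f"feature columns missing from table: {missing}")
        norm = apply_normalization(table[self.feature_names], self.normalization)
        return norm.to_numpy(dtype=float) @ self.weights + self.intercept

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        rs = self.score(table)
        return np.where(rs >= 0, "G2", "G1")

    def to_json(self, path: str | Path) -> None:
        norm = float(np.linalg.norm(self.weights))
        payload = {
            "features": self.feature_names,
            "weights": self.weights.tolist(),
            "unit_weights": (self.weights / norm).tolist() if norm > 0 else self.weights.tolist(),
            "intercept": self.intercept,
            "normalization": {k: list(v) for k, v in self.normalization.items()},
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RadiomicSignature":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=list(payload["features"]),
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=float(payload["intercept"]),
            normalization={k: tuple(v) for k, v in payload["normalization"].items()},
            provenance=payload.get("provenance", {}),
        )


def evaluate_signature(
    signature: RadiomicSignature,
    table: pd.DataFrame,
    seed: int = 0,
) -> dict:
    """RS-based metrics of a signature on a cohort table.

    Reports the AUC of RS (with bootstrap CI), the Wilcoxon p of G1/G2 RS
    separation, and the confusion metrics at the fixed RS = 0 boundary.
    """
    rs = signature.score(table)
    grade = table["grade"].to_numpy()
    roc = roc_auc(rs, grade, positive="G2", seed=seed)
    p = wilcoxon_rank_sum(rs[grade == "G2"], rs[grade == "G1"])
    calls = np.where(rs >= 0, "G2", "G1")
    cm = confusion_metrics(
        tp=int(((calls == "G2") & (grade == "G2")).sum()),
        fp=int(((calls == "G2") & (grade == "G1")).sum()),
        tn=int(((calls == "G1") & (grade == "G1")).sum()),
        fn=int(((calls == "G1") & (grade == "G2")).sum()),
    )
    return {"auc": roc.auc, "auc_ci": roc.ci, "p": p, "confusion": cm, "rs": rs}


def _fit_signature(
    table: pd.DataFrame,
    pair: tuple[str, ...],
    fit_rows,
    provenance: dict | None = None,
) -> RadiomicSignature:
    cols = list(pair)
    normed, params = normalize_features(table, fit_rows, feature_cols=cols)
    lda = RadiomicLDA().fit(normed.loc[fit_rows, cols].to_numpy(dtype=float),
                            table.loc[fit_rows, "grade"].to_numpy())
    return RadiomicSignature(cols, lda.coef_, lda.intercept_, params, provenance or {})


def train_eval_transfer(
    train: pd.DataFrame,
    test: pd.DataFrame,
    pair: tuple[str, ...],
    design: str = "A",
    seed: int = 0,
) -> tuple[RadiomicSignature, dict, dict]:
    """Fit on one cohort, validate on the other (designs A and B).

    Normalization is fitted on the training cohort only and reused on the
    test cohort. Returns the signature plus train and test metric dicts.
    """
    signature = _fit_signature(train, pair, train.index,
                               provenance={"design": design, "n_train": len(train)})
    return (
        signature,
        evaluate_signature(signature, train, seed=seed),
        evaluate_signature(signature, test, seed=seed),
    )


def stratified_folds(table: pd.DataFrame, k: int = 3, seed: int = 0) -> np.ndarray:
    """Random k-fold assignment stratified on (source, grade) cells.

    Each cell contributes floor or ceil of cell/k patients to every fold
    (deviation from exact proportionality < 1); leftover patients go to the
    currently smallest folds so total fold sizes stay balanced.
    """
    rng = np.random.default_rng(seed)
    folds = np.full(len(table), -1, dtype=int)
    sizes = np.zeros(k, dtype=int)
    cells = table.groupby(["source", "grade"], sort=True).indices
    for key in sorted(cells):
        idx = np.asarray(cells[key])
        if len(idx) < k:
            raise ValueError(f"stratification cell {key} has {len(idx)} patients, fewer than k={k}")
        idx = rng.permutation(idx)
        base, extras = divmod(len(idx), k)
        order = rng.permutation(k)
        order = order[np.argsort(sizes[order], kind="stable")]
        counts = np.full(k, base)
        counts[order[:extras]] += 1
        pos = 0
        for f in range(k):
            folds[idx[pos:pos + counts[f]]] = f
            pos += counts[f]
        sizes += counts
    return folds


@dataclass
class CvRunRecord:
    repetition: int
    fold: int
    train_auc: float
    val_auc: float
    overfit: bool
    winner: bool
    signature: RadiomicSignature
    val_confusion: object


@dataclass
class CvSummary:
    """Bookkeeping of a repeated stratified CV (model C).

    ``n_winner_train_side`` / ``n_winner_val_side`` are the two parallel
    accountings of per-repetition best runs (by training and by validation
    AUC respectively) that survive the overfit-discard rule.
    """

    runs: list[CvRunRecord]
    n_runs: int
    n_winners: int
    n_empty_repetitions: int
    n_winner_train_side: int
    n_winner_val_side: int
    averaged_signature: RadiomicSignature | None
    median_winner_val_auc: float
    iqr_winner_val_auc: float
    median_winner_sensitivity: float
    median_winner_specificity: float


def repeated_cv(
    table: pd.DataFrame,
    pair: tuple[str, ...],
    repetitions: int = 100,
    k: int = 3,
    seed: int = 0,
) -> CvSummary:
    """Repeated stratified k-fold CV with overfit discard and winner averaging.

    Per repetition, every fold serves once as validation (k runs). Runs with
    validation AUC strictly greater than training AUC are discarded as
    overfitting-prone; among the survivors the run with the highest
    validation AUC is the repetition's winner (ties broken by lower fold
    index). The final signature averages the winners' weights, intercepts and
    normalization parameters coefficient-wise (weights already point G1->G2
    by construction of the LDA fit).
    """
    rng = np.random.default_rng(seed)
    table = table.reset_index(drop=True)
    runs: list[CvRunRecord] = []
    winners: list[CvRunRecord] = []
    n_empty = 0
    n_train_side = 0
    n_val_side = 0
    for rep in range(1, repetitions + 1):
        fold_of = stratified_folds(table, k=k, seed=int(rng.integers(0, 2**31 - 1)))
        rep_runs = []
        for f in range(k):
            val_rows = table.index[fold_of == f]
            train_rows = table.index[fold_of != f]
            sig = _fit_signature(table, pair, train_rows,
                                 provenance={"design": "C", "repetition": rep, "fold": f})
            rs = sig.score(table)
            grade = table["grade"].to_numpy()
            train_auc = _fast_auc(rs[train_rows], grade[train_rows])
            val_auc = _fast_auc(rs[val_rows], grade[val_rows])
            calls = np.where(rs[val_rows] >= 0, "G2", "G1")
            g = grade[val_rows]
            cm = confusion_metrics(
                tp=int(((calls == "G2") & (g == "G2")).sum()),
                fp=int(((calls == "G2") & (g == "G1")).sum()),
                tn=int(((calls == "G1") & (g == "G1")).sum()),
                fn=int(((calls == "G1") & (g == "G2")).sum()),
            )
            rep_runs.append(CvRunRecord(
                repetition=rep, fold=f, train_auc=train_auc, val_auc=val_auc,
                overfit=val_auc > train_auc, winner=False, signature=sig,
                val_confusion=cm,
            ))
        survivors = [r for r in rep_runs if not r.overfit]
        if survivors:
            best = max(survivors, key=lambda r: (r.val_auc, -r.fold))
            best.winner = True
            winners.append(best)
        else:
            n_empty += 1
        if not max(rep_runs, key=lambda r: (r.train_auc, -r.fold)).overfit:
            n_train_side += 1
        if not max(rep_runs, key=lambda r: (r.val_auc, -r.fold)).overfit:
            n_val_side += 1
        runs.extend(rep_runs)

    averaged = None
    med_auc = iqr_auc = med_sens = med_spec = float("nan")
    if winners:
        weights = np.mean([w.signature.weights for w in winners], axis=0)
        intercept = float(np.mean([w.signature.intercept for w in winners]))
        norm = {
            c: (
                float(np.mean([w.signature.normalization[c][0] for w in winners])),
                float(np.mean([w.signature.normalization[c][1] for w in winners])),
            )
            for c in pair
        }
        averaged = RadiomicSignature(list(pair), weights, intercept, norm,
                                     provenance={"design": "C", "n_winners": len(winners)})
        val_aucs = np.array([w.val_auc for w in winners])
        med_auc = float(np.median(val_aucs))
        q75, q25 = np.percentile(val_aucs, [75, 25])
        iqr_auc = float(q75 - q25)
        med_sens = float(np.nanmedian([w.val_confusion.sensitivity for w in winners]))
        med_spec = float(np.nanmedian([w.val_confusion.specificity for w in winners]))
    else:
        logger.warning("repeated CV produced no winners (every repetition discarded)")

    return CvSummary(
        runs=runs,
        n_runs=len(runs),
        n_winners=len(winners),
        n_empty_repetitions=n_empty,
        n_winner_train_side=n_train_side,
        n_winner_val_side=n_val_side,
        averaged_signature=averaged,
        median_winner_val_auc=med_auc,
        iqr_winner_val_auc=iqr_auc,
        median_winner_sensitivity=med_sens,
        median_winner_specificity=med_spec,
    )


def _fast_auc(scores: np.ndarray, grade: np.ndarray) -> float:
    """Mann-Whitney AUC (ties counted 1/2) from rank sums."""
    from scipy.stats import rankdata

    pos = grade == "G2"
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both grades must appear in every fold")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def predict(signature: RadiomicSignature, table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient radiomic score and grade call at the RS = 0 boundary."""
    rs = signature.score(table)
    if np.any(rs == 0):
        logger.warning("radiomic score exactly 0 for %d case(s); called G2", int((rs == 0).sum()))
    out = pd.DataFrame({"id": table["id"], "rs": rs, "call": np.where(rs >= 0, "G2", "G1")})
    return out.set_index(table.index)
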