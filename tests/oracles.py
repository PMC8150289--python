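"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (double loops, exhaustive enumeration)
and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# in-plane integer offsets (dx, dy) for the four canonical angles at distance
# d, in the implementation's angle order (0, 45, 90, 135 degrees); signs are
# immaterial after symmetrization
ANGLE_OFFSETS = lambda d: [(0, d), (d, d), (d, 0), (d, -d)]  # noqa: E731


def glcm_counts_bruteforce(levels: np.ndarray, mask: np.ndarray, d: int) -> np.ndarray:
    """Per-angle symmetrized pair counts by exhaustive voxel-pair enumeration.

    ``levels`` is a 3D integer array (levels 1..n inside the mask); pairs are
    in-plane (fixed z). Returns (n, n, 4) counts.
    """
    n = int(levels[mask].max())
    out = np.zeros((n, n, 4), dtype=np.int64)
    nx, ny, nz = levels.shape
    for a, (dx, dy) in enumerate(ANGLE_OFFSETS(d)):
        for z in range(nz):
            for x in range(nx):
                for y in range(ny):
                    if not mask[x, y, z]:
                        continue
                    x2, y2 = x + dx, y + dy
                    if not (0 <= x2 < nx and 0 <= y2 < ny):
                        continue
                    if not mask[x2, y2, z]:
                        continue
                    i, j = levels[x, y, z] - 1, levels[x2, y2, z] - 1
                    out[i, j, a] += 1
                    out[j, i, a] += 1
    return out


def second_order_direct(p: np.ndarray) -> dict:
    """All 12 second-order features by direct double summation."""
    n = p.shape[0]
    mu_i = sum((i + 1) * p[i, j] for i in range(n) for j in range(n))
    mu_j = sum((j + 1) * p[i, j] for i in range(n) for j in range(n))
    var_i = sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(n) for j in range(n))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    out = {
        "energy": sum(p[i, j] ** 2 for i in range(n) for j in range(n)),
        "E": -sum(p[i, j] * math.log2(p[i, j]) for i in range(n) for j in range(n) if p[i, j] > 0),
        "contrast": sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n)),
        "dissimilarity": sum(abs(i - j) * p[i, j] for i in range(n) for j in range(n)),
        "homogeneity": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)),
        "NH": sum(p[i, j] / (1 + ((i - j) / n) ** 2) for i in range(n) for j in range(n)),
        "autocorrelation": sum((i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n)),
        "cluster_shade": sum((i + j + 2 - mu_i - mu_j) ** 3 * p[i, j]
                             for i in range(n) for j in range(n)),
        "cluster_prominence": sum((i + j + 2 - mu_i - mu_j) ** 4 * p[i, j]
                                  for i in range(n) for j in range(n)),
        "max_prob": p.max(),
        "sum_average": sum((i + j + 2) * p[i, j] for i in range(n) for j in range(n)),
    }
    if var_i > 0 and var_j > 0:
        out["correlation"] = sum(
            (i + 1 - mu_i) * (j + 1 - mu_j) * p[i, j] for i in range(n) for j in range(n)
        ) / math.sqrt(var_i * var_j)
    else:
        out["correlation"] = 1.0
    return out


def auc_paircount(scores, labels, positive) -> float:
    """AUC by exhaustive pair counting, ties worth 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    s_pos, s_neg = scores[pos], scores[~pos]
    total = 0.0
    for a in s_pos:
        for b in s_neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (s_pos.size * s_neg.size)


def wilcoxon_exact_enumeration(x, y) -> float:
    """Two-sided rank-sum p by enumerating every group assignment (tiny n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    order = pooled.argsort()
    ranks = np.empty_like(pooled)
    ranks[order] = np.arange(1, pooled.size + 1)
    n1 = x.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = pooled.size
    mean_u = n1 * (n - n1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = sum(ranks[list(combo)]) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def skewness_kurtosis_textbook(vals) -> tuple[float, float]:
    """Biased moment-ratio skewness and (Pearson) kurtosis."""
    vals = np.asarray(vals, dtype=float)
    mu = vals.mean()
    m2 = ((vals - mu) ** 2).mean()
    m3 = ((vals - mu) ** 3).mean()
    m4 = ((vals - mu) ** 4).mean()
    return m3 / m2 ** 1.5, m4 / m2 ** 2


def fisher_ratio(w, X, y, positive) -> float:
    """Between/within variance ratio of the projection X @ w."""
    z = X @ w
    pos = np.asarray(y) == positive
    zb = z[pos].mean() - z[~pos].mean()
    within = z[pos].var(ddof=1) * (pos.sum() - 1) + z[~pos].var(ddof=1) * ((~pos).sum() - 1)
    return zb ** 2 / within


def icc_a1_hand(a, b) -> float:
    """ICC(A,1) from explicitly written-out ANOVA sums of squares."""
    data = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * sum((data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
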