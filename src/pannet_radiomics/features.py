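"""The 60-feature radiomic vector: first-order SUV statistics and GLCM texture.

The vector comprises 12 first-order features computed on the raw SUV values
inside the lesion mask, plus 12 second-order (Haralick-family) features on
each of four grey-level co-occurrence matrices at in-plane distances
d = 1..4 voxels, quantized at 64 grey levels — 60 features in total.

GLCMs are 2D in-plane, accumulated over transaxial slices: for each slice and
each of the four canonical angles {0, 45, 90, 135} degrees, ordered level
pairs at offset length d are counted with both voxels inside the mask, counts
are summed over slices, symmetrized, normalized per angle, and the four
normalized matrices are averaged.

The per-family feature definitions live in small registries
(:data:`FIRST_ORDER_REGISTRY`, :data:`SECOND_ORDER_REGISTRY`) so an
individual formula can be swapped without touching the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix
from sklearn.preprocessing import MinMaxScaler

from .imgio import LesionMask, SuvVolume
from .segmentation import check_eligibility

logger = logging.getLogger(__name__)

__all__ = [
    "QuantizedLesion",
    "Glcm",
    "quantize",
    "compute_glcm",
    "glcm_counts",
    "first_order_features",
    "second_order_features",
    "extract_feature_vector",
    "normalize_features",
    "FEATURE_NAMES",
    "FIRST_ORDER_REGISTRY",
    "SECOND_ORDER_REGISTRY",
]

DEFAULT_N_LEVELS = 64
DEFAULT_DISTANCES = (1, 2, 3, 4)
# in-plane angles in radians; offsets (0,d), (d,d), (d,0), (-d,d) up to symmetry
ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass
class QuantizedLesion:
    """Integer grey levels 1..n_levels inside the mask; 0 outside."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        self.mask = np.asarray(self.mask).astype(bool)
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("quantized levels must lie in 1..n_levels inside the mask")


@dataclass
class Glcm:
    """Symmetric, angle-averaged, normalized co-occurrence matrix at distance d."""

    matrix: np.ndarray
    d: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("GLCM must be a square matrix")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("GLCM must be symmetric")
        if m.min() < 0 or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM entries must be >= 0 and sum to 1")
        self.matrix = m

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]


def quantize(volume: SuvVolume, mask: LesionMask, n_levels: int = DEFAULT_N_LEVELS) -> QuantizedLesion:
    """Equal-width binning of the masked SUV range into ``n_levels`` levels.

    level(v) = min(floor((v - min)/(max - min) * n_levels) + 1, n_levels); a
    constant lesion maps entirely to level 1.
    """
    mask.check_aligned(volume)
    m = mask.values
    vals = volume.values[m]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.values.shape, dtype=np.int64)
    if vmax > vmin:
        scaled = (volume.values[m] - vmin) / (vmax - vmin) * n_levels
        levels[m] = np.minimum(np.floor(scaled).astype(np.int64) + 1, n_levels)
    else:
        levels[m] = 1
    return QuantizedLesion(levels, m, n_levels, (vmin, vmax))


def glcm_counts(q: QuantizedLesion, d: int, angles=ANGLES) -> np.ndarray:
    """Symmetrized in-mask pair counts per angle, summed over transaxial slices.

    Returns an (n_levels, n_levels, n_angles) integer array; the normalized,
    angle-averaged matrix of :func:`compute_glcm` derives from it.
    """
    if d < 1:
        raise ValueError("distance must be >= 1")
    n = q.n_levels
    # diagonal angles use a Chebyshev offset of exactly (+/-d, d), so the
    # distance passed to the underlying kernel is d*sqrt(2) for them (the
    # kernel rounds the projected offsets)
    distances = [d if abs(np.sin(2 * a)) < 1e-9 else d * np.sqrt(2.0) for a in angles]
    # reserve level 0 for outside-mask voxels; drop its row/column afterwards
    counts = np.zeros((n + 1, n + 1, len(angles)), dtype=np.int64)
    img = np.where(q.mask, q.levels, 0).astype(np.uint16 if n < 65535 else np.uint32)
    for z in range(img.shape[2]):
        sl = img[:, :, z]
        if not sl.any():
            continue
        for k, (dist, angle) in enumerate(zip(distances, angles)):
            counts[:, :, k] += graycomatrix(sl, distances=[dist], angles=[angle],
                                            levels=n + 1, symmetric=True,
                                            normed=False)[:, :, 0, 0]
    return counts[1:, 1:, :]


def compute_glcm(q: QuantizedLesion, d: int, angles=ANGLES) -> Glcm:
    """Angle-averaged symmetric GLCM at in-plane distance ``d`` (voxel units).

    Pair counts are accumulated over transaxial (fixed-z) slices with both
    voxels inside the mask; each angle's symmetrized count matrix is
    normalized to sum 1 and the normalized matrices are averaged. Angles with
    no valid pair are dropped from the average; if no angle has a valid pair
    the lesion is too small for this distance and an error is raised.
    """
    counts = glcm_counts(q, d, angles).astype(float)
    totals = counts.sum(axis=(0, 1))
    valid = totals > 0
    if not valid.any():
        raise ValueError(f"no voxel pair at distance {d} lies inside the mask for any angle")
    normalized = counts[:, :, valid] / totals[valid]
    return Glcm(normalized.mean(axis=2), d)


# ---------------------------------------------------------------------------
# First-order features


def _histogram_probs(vals: np.ndarray, n_bins: int) -> np.ndarray:
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return np.array([1.0])
    hist, _ = np.histogram(vals, bins=n_bins, range=(vmin, vmax))
    return hist / hist.sum()


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _skewness(vals: np.ndarray) -> float:
    m2 = np.mean((vals - vals.mean()) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((vals - vals.mean()) ** 3) / m2 ** 1.5)


def _kurtosis(vals: np.ndarray) -> float:
    # Pearson (non-excess) kurtosis; 0 by convention for a constant input
    m2 = np.mean((vals - vals.mean()) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((vals - vals.mean()) ** 4) / m2 ** 2)


# same fixed ordering convention as the second-order registry: the
# signature-relevant entropy comes first for deterministic tie-breaks
FIRST_ORDER_REGISTRY = {
    "E": lambda v: _entropy_bits(_histogram_probs(v, DEFAULT_N_LEVELS)),
    "mean": lambda v: float(v.mean()),
    "variance": lambda v: float(v.var()),
    "skewness": _skewness,
    "kurtosis": _kurtosis,
    "min": lambda v: float(v.min()),
    "max": lambda v: float(v.max()),
    "range": lambda v: float(v.max() - v.min()),
    "rms": lambda v: float(np.sqrt(np.mean(v ** 2))),
    "cv": lambda v: float(v.std() / v.mean()) if v.mean() != 0 else 0.0,
    "energy": lambda v: float(np.sum(v ** 2)),
    "uniformity": lambda v: float(np.sum(_histogram_probs(v, DEFAULT_N_LEVELS) ** 2)),
}


def first_order_features(volume: SuvVolume, mask: LesionMask) -> dict[str, float]:
    """The 12 first-order features on the masked SUV values.

    Histogram-based features (uniformity, entropy E_SUV) use a 64-bin
    histogram over the masked [min, max] range. A constant lesion gives
    entropy 0, uniformity 1 and skewness/kurtosis 0 by convention.
    """
    mask.check_aligned(volume)
    vals = volume.values[mask.values].astype(float)
    return {f"{name}_SUV": fn(vals) for name, fn in FIRST_ORDER_REGISTRY.items()}


# ---------------------------------------------------------------------------
# Second-order (GLCM) features


def _glcm_stats(p: np.ndarray):
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)[:, None] * np.ones((1, n))
    j = i.T
    return i, j


def _so_correlation(p, i, j):
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    var_i = ((i - mu_i) ** 2 * p).sum()
    var_j = ((j - mu_j) ** 2 * p).sum()
    if var_i == 0 or var_j == 0:
        return 1.0  # degenerate single-level lesion: perfectly correlated
    return float(((i - mu_i) * (j - mu_j) * p).sum() / np.sqrt(var_i * var_j))


def _so_cluster(p, i, j, power):
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    return float(((i + j - mu_i - mu_j) ** power * p).sum())


# fixed registry order: the signature features (entropy, the homogeneity group)
# first, then the remaining Haralick-family measures — this is the documented
# ordering used for deterministic tie-breaks in the selection stage
SECOND_ORDER_REGISTRY = {
    "E": lambda p, i, j: _entropy_bits(p.ravel()),
    "NH": lambda p, i, j: float((p / (1.0 + ((i - j) / p.shape[0]) ** 2)).sum()),
    "homogeneity": lambda p, i, j: float((p / (1.0 + (i - j) ** 2)).sum()),
    "contrast": lambda p, i, j: float(((i - j) ** 2 * p).sum()),
    "dissimilarity": lambda p, i, j: float((np.abs(i - j) * p).sum()),
    "correlation": _so_correlation,
    "energy": lambda p, i, j: float((p ** 2).sum()),
    "max_prob": lambda p, i, j: float(p.max()),
    "autocorrelation": lambda p, i, j: float((i * j * p).sum()),
    "sum_average": lambda p, i, j: float(((i + j) * p).sum()),
    "cluster_shade": lambda p, i, j: _so_cluster(p, i, j, 3),
    "cluster_prominence": lambda p, i, j: _so_cluster(p, i, j, 4),
}


def second_order_features(glcm: Glcm) -> dict[str, float]:
    """The 12 second-order features of a normalized GLCM.

    Includes the entropy E_GLCM = -sum p log2 p and the normalized
    homogeneity NH_GLCM = sum p(i,j) / (1 + ((i-j)/N_g)^2), which lies in
    (0, 1] and equals 1 exactly when all mass sits on the diagonal.
    """
    p = np.asarray(glcm.matrix, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("second-order features require a normalized GLCM")
    i, j = _glcm_stats(p)
    return {f"{name}_GLCM-{glcm.d}": fn(p, i, j) for name, fn in SECOND_ORDER_REGISTRY.items()}


# fixed feature ordering: the second-order (GLCM) block first — the signature
# and the screening narrative centre on it — then the first-order block; this
# is the documented ordering behind every deterministic tie-break
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{name}_GLCM-{d}" for d in DEFAULT_DISTANCES for name in SECOND_ORDER_REGISTRY]
    + [f"{name}_SUV" for name in FIRST_ORDER_REGISTRY]
)


def extract_feature_vector(
    volume: SuvVolume,
    mask: LesionMask,
    distances=DEFAULT_DISTANCES,
    n_levels: int = DEFAULT_N_LEVELS,
) -> dict[str, float]:
    """The full radiomic vector: 12 first-order + 12 per GLCM distance."""
    eligible, reason = check_eligibility(mask, min_voxels=n_levels)
    if not eligible:
        raise ValueError(f"mask not eligible for feature extraction: {reason}")
    out: dict[str, float] = {}
    q = quantize(volume, mask, n_levels)
    for d in distances:
        out.update(second_order_features(compute_glcm(q, d)))
    out.update(first_order_features(volume, mask))
    return out


# ---------------------------------------------------------------------------
# Normalization


def normalize_features(
    table: pd.DataFrame,
    fit_rows,
    feature_cols=None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per-feature min-max scaling fitted on the training rows.

    The scaling is fitted on ``table.loc[fit_rows]`` and applied to every row;
    test rows may legitimately fall outside [0, 1]. Zero-range features map to
    0 with a logged warning. Returns the scaled table and the per-feature
    (min, max) parameters for test-time reuse.
    """
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_NAMES if c in table.columns]
    fit = table.loc[fit_rows, feature_cols]
    if fit.empty:
        raise ValueError("fit_rows must select at least one row")
    scaler = MinMaxScaler().fit(fit.to_numpy(dtype=float))
    zero_range = [c for c, lo, hi in zip(feature_cols, scaler.data_min_, scaler.data_max_) if hi == lo]
    if zero_range:
        logger.warning("zero-range features mapped to 0: %s", zero_range)
    out = table.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # sklearn feature-name check
        out[feature_cols] = scaler.transform(table[feature_cols].to_numpy(dtype=float))
    params = {c: (float(lo), float(hi)) for c, lo, hi in
              zip(feature_cols, scaler.data_min_, scaler.data_max_)}
    return out, params


def apply_normalization(table: pd.DataFrame, params: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Re-apply stored min-max parameters (the deployed-model scenario)."""
    out = table.copy()
    for col, (lo, hi) in params.items():
        rng = hi - lo
        out[col] = (table[col] - lo) / rng if rng > 0 else table[col] - lo
    return out
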