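"""Synthetic SUV lesion phantoms and cohorts for exercising the pipeline.

The patient images behind the grading analysis are private, so this module
generates seeded phantoms with the statistical structure the analysis
assumes. Each lesion is an ellipsoid (mild random eccentricity) embedded in
a uniform background, carrying a zero-mean unit-variance random texture
built from three variance components:

* a *clump* component — block-constant noise on an ~11 mm cell grid,
  emulating patches of locally uniform uptake ("habitat" clumps). Clump
  texture puts co-occurrence mass on the exact-equality diagonal, which is
  what inverse-difference (homogeneity) features measure;
* a *fine* component — Gaussian-correlated noise at a short correlation
  length (default 2.4 mm), a continuous granular texture;
* a *long-range* component — Gaussian-correlated noise at a long
  correlation length (default 14 mm), a smooth background gradient that
  keeps distant voxels correlated.

The component weights of the clump and fine fields are chosen so the
short-range autocorrelation of the two grade classes matches: the grade
contrast is carried by the *form* of the local structure (clumped vs
granular — the local-homogeneity axis) and by the long-range component
share and lesion size (far-range disorder — the entropy axis), not by
nuisance statistics. The texture is winsorized at +/-1.8 SD so the min-max
quantization range, and with it every histogram-shape feature, is
grade-neutral. Higher-grade (G2) phantoms are drawn with more clump weight,
less long-range weight and the larger size distribution reported for
higher-grade tumours; mean uptake is drawn from one shared distribution so
SUVmax carries no grade signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imgio import LesionMask, SuvVolume
from .segmentation import suv_max

__all__ = ["PhantomSpec", "CohortSpec", "generate_lesion", "generate_cohort", "make_glcm_fixture"]

DEFAULT_SPACING = (3.75, 3.75, 3.75)  # mm, a common PET reconstruction grid

# grade-class texture parameters: component weights (clump, fine, long-range)
G1_WEIGHTS = np.array([0.005, 0.62, 0.375])
G2_WEIGHTS = np.array([0.72, 0.23, 0.05])
# lesion diameter: log-normal, medians ~27 mm (G1) and ~36 mm (G2 at full effect)
G1_LOG_DIAMETER = np.log(27.0)
G2_LOG_DIAMETER_SHIFT = 0.30
LOG_DIAMETER_SD = 0.14
DIAMETER_RANGE_MM = (23.0, 60.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic lesion phantom.

    ``clump_weight``, ``fine_weight`` and ``long_range_weight`` are the
    variance shares of the three texture components (normalized internally);
    ``texture_noise_sd`` is the total texture standard deviation in SUV units
    (0 gives a constant lesion). The two correlation lengths and the clump
    cell size are in millimetres.
    """

    grade_label: str = "G1"
    lesion_radius_mm: float = 15.0
    background_suv: float = 1.0
    lesion_mean_suv: float = 30.0
    texture_noise_sd: float = 6.0
    clump_weight: float = 0.005
    fine_weight: float = 0.62
    long_range_weight: float = 0.375
    clump_cell_mm: float = 11.25
    fine_correlation_length_mm: float = 2.4
    long_correlation_length_mm: float = 14.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade_label not in ("G1", "G2"):
            raise ValueError(f"grade_label must be G1 or G2, got {self.grade_label!r}")
        if not self.lesion_mean_suv > self.background_suv > 0:
            raise ValueError("need lesion_mean_suv > background_suv > 0")
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")
        if min(self.clump_weight, self.fine_weight, self.long_range_weight) < 0:
            raise ValueError("texture component weights must be >= 0")
        if self.clump_weight + self.fine_weight + self.long_range_weight <= 0:
            raise ValueError("at least one texture component weight must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Composition and effect structure of a synthetic two-source cohort.

    Default counts (13 G1 / 12 G2 histology-graded, 18 G1 / 8 G2
    biopsy-graded) match the 51-patient study population the pipeline is
    designed around. ``grade_effect_size`` scales every grade contrast
    (texture weights and size shift); 0 makes the grades exchangeable (a
    null cohort). The default size range keeps every lesion above the
    64-voxel eligibility bound so the default cohort needs no exclusions.
    """

    n_hs_g1: int = 13
    n_hs_g2: int = 12
    n_bs_g1: int = 18
    n_bs_g2: int = 8
    grade_effect_size: float = 1.0
    size_range_mm: tuple[float, float] = DIAMETER_RANGE_MM
    seed: int = 0
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        if min(self.n_hs_g1, self.n_hs_g2, self.n_bs_g1, self.n_bs_g2) < 0:
            raise ValueError("cohort counts must be >= 0")
        lo, hi = self.size_range_mm
        if not 0 < lo <= hi:
            raise ValueError(f"invalid size range {self.size_range_mm}")


def _block_noise(rng: np.random.Generator, shape, cell: int) -> np.ndarray:
    """Block-constant white noise on a coarse cell grid with a random offset."""
    coarse = rng.standard_normal(tuple(s // cell + 2 for s in shape))
    up = np.kron(coarse, np.ones((cell,) * 3))
    off = rng.integers(0, cell, 3)
    return up[off[0]:off[0] + shape[0], off[1]:off[1] + shape[1], off[2]:off[2] + shape[2]]


def generate_lesion(
    spec: PhantomSpec,
    grid_shape: tuple[int, int, int] = (24, 24, 24),
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> tuple[SuvVolume, LesionMask]:
    """One ellipsoidal textured lesion embedded in a uniform background.

    Output is bit-identical for identical specs (the seed drives all
    randomness); a lesion that does not fit in the grid with a 2-voxel
    margin raises.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(voxel_spacing, dtype=float)
    shape = tuple(int(s) for s in grid_shape)

    ecc = rng.uniform(-0.15, 0.15, size=3)
    semi_axes_vox = spec.lesion_radius_mm * (1.0 + ecc) / spacing
    center = (np.asarray(shape) - 1) / 2.0
    if np.any(semi_axes_vox + 2.0 > np.asarray(shape) / 2.0):
        raise ValueError(
            f"lesion (semi-axes {semi_axes_vox} voxels) exceeds grid {shape} "
            "with the required 2-voxel margin"
        )

    grids = np.indices(shape, dtype=float)
    dist2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes_vox))
    mask = dist2 <= 1.0

    values = np.full(shape, spec.background_suv, dtype=float)
    if spec.texture_noise_sd > 0 and int(mask.sum()) > 1:
        def unit(field: np.ndarray) -> np.ndarray:
            inside = field[mask]
            sd = inside.std()
            return (field - inside.mean()) / sd if sd > 0 else np.zeros(shape)

        cell = max(1, int(round(spec.clump_cell_mm / spacing.max())))
        clump = unit(_block_noise(rng, shape, cell))
        fine = unit(gaussian_filter(rng.standard_normal(shape),
                                    sigma=spec.fine_correlation_length_mm / spacing))
        longr = unit(gaussian_filter(rng.standard_normal(shape),
                                     sigma=spec.long_correlation_length_mm / spacing))
        w = np.array([spec.clump_weight, spec.fine_weight, spec.long_range_weight])
        w = w / w.sum()
        tex = np.sqrt(w[0]) * clump + np.sqrt(w[1]) * fine + np.sqrt(w[2]) * longr
        tex = np.clip(unit(tex), -1.8, 1.8)  # winsorize: fixed quantization range
        values[mask] = np.maximum(spec.lesion_mean_suv + spec.texture_noise_sd * tex[mask], 0.0)
    else:
        values[mask] = spec.lesion_mean_suv

    return SuvVolume(values, tuple(spacing)), LesionMask(mask, tuple(spacing))


def grade_texture_weights(grade: str, effect: float) -> np.ndarray:
    """Texture component weights for a grade at a given effect size."""
    if grade == "G2":
        return G1_WEIGHTS + effect * (G2_WEIGHTS - G1_WEIGHTS)
    return G1_WEIGHTS.copy()


def patient_seed(master_seed: int, index: int) -> int:
    """Per-patient seed derived from the cohort master seed via a counter."""
    return (master_seed * 1_000_003 + 7919 * index) % (2**31 - 1)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, tuple[SuvVolume, LesionMask]], pd.DataFrame]:
    """A full synthetic cohort: phantoms keyed by patient id plus a metadata table.

    The table has columns id, grade, source, size_mm, seed, suvmax. Besides
    the grade shift, each patient receives a jitter along the grade axis of
    the texture weights, an independent long-range-weight jitter in both
    grades (a nuisance that de-sharpens per-lesion autocorrelation
    estimates) and an independent lesion size; mean uptake is drawn from one
    shared distribution so the SUVmax effect size between grades is ~0.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    e = spec.grade_effect_size
    axis = G2_WEIGHTS - G1_WEIGHTS
    axis = axis / np.linalg.norm(axis)
    groups = [
        ("HS", "G1", spec.n_hs_g1),
        ("HS", "G2", spec.n_hs_g2),
        ("BS", "G1", spec.n_bs_g1),
        ("BS", "G2", spec.n_bs_g2),
    ]
    phantoms: dict[str, tuple[SuvVolume, LesionMask]] = {}
    rows = []
    index = 0
    for source, grade, count in groups:
        for _ in range(count):
            index += 1
            pid = f"P{index:03d}"
            w = grade_texture_weights(grade, e) + rng.normal(0.0, 0.12) * axis * e
            w[2] += rng.uniform(-0.16, 0.16)
            w = np.clip(w + rng.normal(0.0, 0.02, 3), 0.005, None)
            w = w / w.sum()
            mlog = G1_LOG_DIAMETER + (G2_LOG_DIAMETER_SHIFT * e if grade == "G2" else 0.0)
            dia = float(np.clip(np.exp(rng.normal(mlog, LOG_DIAMETER_SD)),
                                *spec.size_range_mm))
            mean_suv = float(rng.uniform(12.0, 70.0))
            pspec = PhantomSpec(
                grade_label=grade,
                lesion_radius_mm=dia / 2.0,
                background_suv=1.0,
                lesion_mean_suv=mean_suv,
                texture_noise_sd=0.2 * mean_suv,
                clump_weight=float(w[0]),
                fine_weight=float(w[1]),
                long_range_weight=float(w[2]),
                seed=patient_seed(spec.seed, index),
            )
            # grid sized to the lesion plus margin for dilation sweeps
            half = np.ceil(dia / 2.0 * 1.16 / spacing).astype(int) + 4
            grid = tuple(int(2 * h + 1) for h in half)
            vol, mask = generate_lesion(pspec, grid, tuple(spacing))
            phantoms[pid] = (vol, mask)
            rows.append({
                "id": pid,
                "grade": grade,
                "source": source,
                "size_mm": dia,
                "seed": pspec.seed,
                "suvmax": suv_max(vol, mask),
            })
    return phantoms, pd.DataFrame(rows)


def make_glcm_fixture(
    pattern: str,
    shape: tuple[int, int] = (4, 4),
    seed: int = 0,
    n_levels: int = 8,
):
    """Tiny single-slice quantized images whose GLCMs are hand-computable.

    Patterns: ``constant`` (all level 1), ``checkerboard`` (levels 1/2),
    ``ramp`` (level increases along the first axis, wrapping at ``n_levels``)
    and ``random`` (seeded uniform levels).
    """
    from .features import QuantizedLesion

    nx, ny = int(shape[0]), int(shape[1])
    if nx < 2 or ny < 2:
        raise ValueError("fixture shape must be at least 2x2")
    if pattern == "constant":
        img = np.ones((nx, ny), dtype=np.int64)
        levels = 1
    elif pattern == "checkerboard":
        xx, yy = np.indices((nx, ny))
        img = ((xx + yy) % 2) + 1
        levels = 2
    elif pattern == "ramp":
        xx = np.indices((nx, ny))[0]
        img = (xx % n_levels) + 1
        levels = n_levels
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        img = rng.integers(1, n_levels + 1, size=(nx, ny))
        levels = n_levels
    else:
        raise ValueError(f"unknown fixture pattern {pattern!r}")
    img3 = img[:, :, None]
    mask = np.ones_like(img3, dtype=bool)
    return QuantizedLesion(img3, mask, levels, (1.0, float(levels)))
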