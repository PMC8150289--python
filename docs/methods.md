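# Methods

This note documents the models, procedures, parameters and design choices
behind `pannet_radiomics`: a pipeline that predicts WHO grade (G1 vs G2) of
pancreatic neuroendocrine tumours from somatostatin-receptor PET SUV maps via
grey-level co-occurrence texture features and a two-feature linear
discriminant signature. The patient data underlying the original study is
private, so the package is exercised end-to-end on seeded synthetic lesion
phantoms whose construction is described below.

## Segmentation

Lesions arrive as a SUV volume plus a manually delineated region of interest
(ROI). The segmentation keeps ROI voxels with SUV >= 0.40 x SUVmax (the ROI's
hottest voxel) and then retains the 26-connected component containing that
voxel. Two conventions are deliberate:

* the threshold inequality is `>=`, which makes segmentation idempotent and
  guarantees the SUVmax voxel always survives;
* connected-component selection uses 26-connectivity in 3D; whether the
  original manual workflow applied component selection at all is unknown, so
  this is an interpretation, flagged here.

A lesion is *eligible* for texture analysis when its mask holds at least 64
voxels — the weakest defensible reading of "too small to generate a 64-level
GLCM"; the bound is configurable. Ineligible lesions are excluded and logged.

## Feature vector (60 features)

Twelve first-order features are computed on the raw masked SUV values: mean,
variance, skewness (m3/m2^1.5), kurtosis (Pearson m4/m2^2; both defined as 0
for a constant input), min, max, range, root-mean-square, coefficient of
variation, energy (sum of squares), and 64-bin-histogram uniformity and
entropy (E_SUV, bits). Twelve second-order features are computed on each of
four GLCMs (distances d = 1..4 voxels): entropy E, normalized homogeneity
NH = sum p(i,j)/(1 + ((i-j)/N_g)^2), homogeneity (inverse difference moment),
contrast, dissimilarity, correlation, energy (angular second moment), maximum
probability, autocorrelation, sum average, cluster shade and cluster
prominence. 12 + 4 x 12 = 60.

GLCMs are built per transaxial slice in 2D using the four canonical angles
{0, 45, 90, 135} degrees with integer offsets (0,d), (d,d), (d,0), (-d,d) —
both voxels must lie in the mask. Counts are summed over slices,
symmetrized, normalized per angle, and the four normalized matrices averaged.
2D-in-plane (rather than 13-direction 3D) matches the four-angle convention
and the transaxial delineation workflow. Quantization is equal-width binning
of the masked [min, max] SUV range into 64 levels; a constant lesion maps to
level 1 throughout. Entropies use log base 2 with 0 log 0 = 0.

The exact membership of the two 12-feature sets is not fully documented in
the original study's public description; the sets above are standard first-order and
Haralick-family choices constrained to include the four features the analysis
names (E_SUV, NH, E_GLCM, homogeneity). Each formula lives in a registry
(`FIRST_ORDER_REGISTRY`, `SECOND_ORDER_REGISTRY`) so an individual definition
can be swapped without touching the pipeline.

**Fixed feature ordering.** Every deterministic tie-break (deduplication
order, winner ties) uses one documented ordering: the second-order block
first (distances ascending, and within each distance E, NH, homogeneity
first — the signature's features), then the first-order block (E first).

**Normalization** is per-feature min-max scaling fitted on the training
cohort and re-applied, unchanged, to validation data (which may therefore
legitimately leave [0, 1]). Min-max was chosen because the published
signature coefficients place the decision boundary near feature values of
0.5, consistent with [0, 1]-scaled inputs.

## Statistics

* Wilcoxon rank-sum (two-tailed): exact null distribution (cached dynamic
  programme per sample-size pair) for tie-free samples with combined n <= 25;
  tie-corrected, continuity-corrected normal approximation otherwise. The
  exact path makes screening thousands of couples cheap (O(1) p lookups).
* AUC equals the Mann-Whitney statistic with ties counted 1/2; 95% CIs use a
  stratified bootstrap (2000 resamples, seeded) — assumption-light at n = 25,
  where DeLong's normality is doubtful.
* Youden index YI = max(sensitivity + specificity - 1) over cutoffs
  (midpoints between consecutive distinct scores); ties break toward higher
  specificity, clinically conservative for a G2 call.
* Holm-Bonferroni step-down with adjusted p = running max of (m-rank+1) x p.
* ICC is ICC(A,1): two-way mixed effects, absolute agreement, single
  measurement, from the ANOVA mean squares. The specific ICC form was not
  stated in the original study; absolute agreement is the conservative choice for
  "same feature, perturbed segmentation".

## Selection

On the histology-graded training cohort only:

1. *Deduplication*: walking the fixed feature ordering, a single feature is
   dropped when |rho| >= 0.90 with an already-kept feature.
2. *Couples*: all unordered couples of the deduplicated singles with mutual
   |rho| <= 0.30. Couples are formed from deduplicated singles (not all 1770
   raw couples) so the multiple-testing family stays small enough for a
   moderately separating couple to clear the Holm gate — with all 1770
   couples in one family, a couple at p ~ 2e-4 could never survive at
   alpha = 0.05, contradicting the published arithmetic of the winning
   couple. The raw total (1770) is still reported.
3. Correlations in steps 1–2 are *class-conditional* (features centred per
   grade before correlating): two features that co-vary only because each
   separates the grades carry complementary, not redundant, information; the
   pooled correlation of a jointly discriminative couple is induced by the
   class signal itself, and filtering on it would discard exactly the couples
   the method is looking for. Class-conditional redundancy is the standard
   notion in the feature-selection literature.
4. *Screening*: singles by the Wilcoxon p of their grade separation, couples
   by the Wilcoxon p of their LDA radiomic-score separation; Holm-corrected
   with singles and couples as separate families (the family definition was
   left open in the original description).
5. *Ranking*: survivors ordered by (p ascending, AUC descending); ties
   resolve by the fixed ordering. The winners are the top single and couple.

## Signature and models

The radiomic signature is an equal-prior two-class LDA on the normalized
winning couple: w = S_pooled^-1 (mu_G2 - mu_G1), b = -w.(mu_G1 + mu_G2)/2
(ridge 1e-6 x I if the pooled covariance is singular). The radiomic score is
RS(x) = w.x + b; RS = 0 is the decision boundary, RS > 0 calls G2, and an
exact RS = 0 is called G2 with a logged warning (conservative toward the
higher grade). Classification depends only on the sign, so coefficient scale
is arbitrary; signature JSON stores both w and w/|w|.

* **Model A** trains on the histology-graded (HS) cohort and validates on the
  biopsy-graded (BS) cohort; **model B** the reverse. Normalization fits on
  the training cohort only.
* **Model C** is 100x repeated stratified 3-fold cross-validation on the
  pooled cohort. Stratification keeps every (source x grade) cell within one
  patient of exact proportionality per fold, distributing remainders to the
  smallest folds (so 51 patients split 17/17/17). Runs whose validation AUC
  strictly exceeds their training AUC are discarded as overfitting-prone
  (equality survives — the rule is implemented literally); among a
  repetition's survivors the highest validation AUC wins, ties to the lower
  fold index. The final signature averages the winners' weights, intercepts
  and normalization parameters coefficient-wise (weights already point
  G1 -> G2 by construction). Because two winner accountings circulate for
  this design, the summary also reports, per repetition, whether the
  best-training-AUC run and the best-validation-AUC run survived the discard
  rule (`n_winner_train_side`, `n_winner_val_side`). Reported informedness is
  always recomputed from the package's own confusion counts; note that a
  median sensitivity and a median specificity generally do not add up to a
  separately quoted informedness, an inconsistency also present in the original study's reported figures.

## Segmentation-perturbation reproducibility

Masks are shrunk/grown to an exact percentage of their original voxel count:
whole morphological passes (3D, face-adjacent structuring element; 26-
connectivity by flag) while they do not overshoot, then individual voxels
removed/added in Euclidean-distance-transform order (boundary-most first for
erosion, nearest-to-mask first for dilation; ties by lexicographic index).
The achieved count matches the target exactly whenever arithmetically
reachable, and the construction guarantees nesting:
erode(r2) ⊆ erode(r1) ⊆ original ⊆ dilate(r1) ⊆ dilate(r2) for r1 < r2.
Erosions that would leave a lesion below the eligibility bound skip that
patient (logged). Sweeps re-extract the signature's features on the
perturbed masks — reusing the original normalization parameters, the
deployed-model scenario (refitting is available by flag) — and report
per-feature ICC against the original extraction, discrimination metrics at
RS = 0, and the symmetric difference of mis-discriminated patient ID sets.
The final thresholded mask is perturbed (not the manual ROI before
thresholding); the alternative reading is noted as open.

## Synthetic cohort generator

Phantoms are axis-aligned ellipsoids (semi-axes jittered +/-15%) in a uniform
unit background on a 3.75 mm isotropic grid, with lesion voxels carrying a
zero-mean, unit-variance texture scaled by `texture_noise_sd` (default
0.2 x lesion mean; 0 gives a constant lesion) and shifted to the requested
mean. The texture mixes three variance components:

* **clump** — block-constant noise on an ~11 mm cell grid with random
  offset: patches of locally uniform uptake. Clump texture puts
  co-occurrence mass on the exact-equality diagonal, the signal that
  inverse-difference (homogeneity) features measure;
* **fine** — Gaussian-correlated noise, correlation length 2.4 mm: a
  continuous granular texture;
* **long-range** — Gaussian-correlated noise, correlation length 14 mm: a
  smooth gradient keeping distant voxels correlated.

Grade classes differ in the component weights — G1 (clump, fine, long) =
(0.005, 0.62, 0.375), G2 = (0.72, 0.23, 0.05), linearly interpolated by
`grade_effect_size` — and in size: log-normal diameters with median 27 mm
(G1) and ~36 mm (G2 at full effect), SD 0.14 on the log scale, clipped to
23–60 mm so every default-cohort lesion is eligible (the published 6–85 mm
range includes lesions that were excluded as too small; that exclusion path
is exercised by dedicated fixtures instead). Mean uptake is drawn from one
shared uniform distribution (12–70 SUV) for both grades, so SUVmax carries
no grade signal by construction. Per-patient nuisance jitters (a shift along
the grade axis of the weight simplex, an independent long-range-weight
jitter, iid weight noise) provide within-grade variability.

Three properties of this construction are deliberate and were calibrated by
forward simulation while designing the generator (not by the acceptance
outcome of any specific run):

1. the clump and fine weights are chosen so the *short-range autocorrelation
   of the two grades matches* — otherwise GLCM-correlation, the statistically
   efficient estimator of an autocorrelation difference, would dominate every
   screen, which is not the structure the grading literature describes;
2. the texture is *winsorized at +/-1.8 SD*, pinning the min-max quantization
   range so histogram-shape features (kurtosis, cluster prominence, range)
   are grade-neutral;
3. grade affects *two separate channels* — local clumpiness (captured by the
   inverse-difference family) and far-range disorder plus size (captured by
   the entropy/orderliness family) — that are independently jittered within
   grade, so the winning couple must combine both axes, mirroring the
   published finding that a local-homogeneity feature pairs with a far-range
   entropy feature at near-zero mutual correlation.

Seeding: one master seed drives cohort-level draws; per-patient seeds derive
from it via a fixed counter formula (`patient_seed`), so individual patients
are reproducible in isolation. All outputs are bit-identical per seed.

What the generator does **not** emulate: PET acquisition physics (Poisson
sinogram noise, point-spread, reconstruction artefacts), partial-volume
effects, background anatomy, multi-lesion patients, and any real biological
link between texture and grade. Passing tests therefore demonstrate that the
*pipeline* recovers effects of the designed form at realistic sample sizes —
not that the radiomic signature generalizes to patients. Two further
honest limitations: the entropy channel is partly lesion-size-driven (as in
the published cohorts, where higher-grade tumours were larger), which makes
the synthetic entropy features less robust to segmentation perturbation than
their patient-data counterparts; and with 25 training patients the
winner-couple identity is itself a noisy maximum statistic — the designed
homogeneity+entropy couple wins in roughly two-thirds of simulated cohorts,
not all of them.

**Feature families** used by the recovery checks group features by texture
axis: *homogeneity* = {NH, homogeneity, contrast, dissimilarity} (local
grey-level difference moments); *entropy* = {E, uniformity, GLCM energy,
maximum probability} (disorder/orderliness measures — angular second moment
and its relatives are the standard inverse duals of entropy). First-order
energy (sum of squared SUV) is an intensity-magnitude feature and belongs to
neither.

## Numerical choices and degenerate inputs

* GLCM angles with no valid pair are dropped from the average; if no angle
  has a pair, the lesion is too small for that distance and extraction
  raises, naming the distance.
* A constant lesion quantizes to level 1 everywhere: E_GLCM = 0, NH = 1,
  contrast = 0, energy = 1; GLCM correlation is defined as 1 for the
  degenerate single-level matrix; first-order skewness/kurtosis are 0.
* Zero-range features map to 0 under min-max normalization (logged).
* Undefined confusion ratios (empty margin) are NaN, never silently 0.
* GLCM symmetry and unit total are validated to 1e-9 at construction.
* Problem sizes in the test suite (cohort counts, repetition counts, null
  replicate counts) are the study's own design sizes where the design states
  them (51 patients, 100 x 3 CV) and otherwise the package's choice,
  documented in the tests.

## Interfaces

NIfTI (.nii/.nii.gz) for volumes (float32) and masks (uint8, diagonal
affine from the voxel spacing); CSV feature tables (one row per patient:
id/grade/source/size/SUVmax plus 60 features); JSON for signatures,
selection reports, run reports and exclusion ledgers; YAML run
configurations (unknown keys rejected; every output stamped with a hash of
the scientific parameters). The `pannet-radgrade` CLI wraps the library
stage by stage (`simulate`, `segment`, `extract`, `select`, `train`,
`perturb`, `report`, `run`).
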