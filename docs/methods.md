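# Methods

## Cubical persistence model

A 2D/3D scalar image is modeled as a cubical complex in the
"T-construction": every voxel is a top-dimensional cube, and every face,
edge and vertex of an included voxel belongs to the complex with value
equal to the **minimum** over the voxels containing it.  The sublevel
filtration activates cells with value ≤ t as t sweeps the 0–255 intensity
scale.  Under this construction two voxels that touch only diagonally
share lower-dimensional cells, so foreground components merge with
26-connectivity-like behavior; all synthetic test instances keep distinct
components at least two voxels apart so their expected topology does not
depend on this convention.

ROI handling: out-of-mask voxels are **excluded** from the complex
entirely (not set to a high value), so no component can merge through
non-ROI tissue at late thresholds.  A cell survives only if at least one
incident voxel is in the mask.

Pairs are computed by GF(2) boundary-matrix column reduction in filtration
order — cells sorted by (value, dimension, lexicographic position) so every
facet precedes its cofaces — with the twist/clearing optimization: cell
dimensions are processed from high to low, and any cell already paired as
the pivot of a higher-dimensional column is skipped, since its own column
must reduce to zero.  H0 is paired by elder-rule union-find over the edges,
which is equivalent to reducing the dim-1 columns but linear-time in
practice.  The inner reduction loops are numba-compiled; a 32³ volume
(~275k cells) takes about half a second end-to-end.

Conventions:

* zero-persistence pairs (birth = death) are discarded;
* classes that never die are closed at the maximum finite filtration value
  and flagged `essential` (kept even when birth equals that maximum, so a
  uniform block yields exactly one H0 pair);
* homology dimensions 0–2 only; H3 cannot occur for complexes embedded in
  R³ and is not tracked.

Two independent oracles guard the implementation: `betti_at_threshold`
computes Betti numbers at a fixed threshold from GF(2) ranks of the full
boundary matrices (Gaussian elimination on bitset rows, no shared code
with the reduction), and `euler_curve` checks the alternating cell-count
identity χ = β0 − β1 (+ β2).  The test suite verifies pair-derived Betti
curves against the rank oracle exhaustively on all 512 binary 3×3 grids
and on 200 random 4³ grids at every distinct threshold.

## Feature vectorization (717 features)

Per homology dimension (H0, H1, H2), seven families totalling 239 values:

| family     | size | definition |
|------------|------|------------|
| stats      | 15   | n_points; lifetime sum/mean/std/median/min/max; birth mean/std/min/max; death mean/std/min/max |
| entropy    | 1    | −Σ (lᵢ/L)·ln(lᵢ/L), L = Σ lᵢ |
| betti      | 30   | #{i: bᵢ ≤ t < dᵢ} at 30 bin centers of [0, 255] |
| landscape  | 150  | λ₁..λ₃ (k-th largest tent max(0, min(t−b, d−t))) at 50 bin centers |
| amplitude  | 3    | distance to the empty diagram: bottleneck max(l)/2; Wasserstein-2 ‖l‖₂/√2; bin-width-scaled L2 norm of the discretized landscape |
| image      | 20   | persistence image on the (birth, persistence) plane: normalized Gaussian kernel σ = 1.0 intensity units, linear persistence weighting, 20×20 grid over [0,255]²; summarized by mean/std/max/sum + 16 mean-pooled 5×5 blocks (row-major) |
| heat       | 20   | signed field Σᵢ [φ_σ(x−pᵢ) − φ_σ(x−p̄ᵢ)] with p̄ the diagonal mirror, same grid and summaries |

Pinned numerical conventions: population (n-denominator) standard
deviations; natural-log entropy with empty/all-zero-lifetime diagrams
mapping to 0; half-open [b, d) activity for Betti curves; σ interpreted in
intensity units; all samplings on the fixed global range [0, 255] so
vectors are comparable across subjects after ROI normalization; empty
diagrams vectorize to zeros throughout.  Points are put in a canonical
(birth, death) sort order before accumulation so the vector is
bit-reproducible under permutations of the diagram.  The per-family split
15+1+30+150+3+20+20 is the smallest natural completion consistent with the
717 total and the landscape/image configuration; only the total and those
configurations are externally fixed.

Feature names follow the `<family>_d<dim>[_l<layer>][_b<bin>]` scheme
(e.g. `landscape_d1_l2_b30`, `betti_d0_b12`, `pi_blk2_3_d0`,
`life_std_d2`); stripping trailing bin/block indices collapses names to
families (`land_d1_l2`, `betti_d0`, `pi_d0`), the unit used for stability
analysis.

## Volume preprocessing

NIfTI I/O via nibabel.  Isotropic resampling uses linear interpolation for
intensities and nearest-neighbor for masks, with output shape
round(n·spacing/target) per axis; resampling an already-isotropic grid is
an exact identity.  ROI normalization maps in-mask intensities affinely to
[0, 255] by in-mask min–max (the window limits are not otherwise
specified, and min–max makes the diagram invariant to affine intensity
rescaling); a constant-intensity ROI maps to all zeros rather than NaN so
the filtration stays defined.  Out-of-mask voxels are never modified.
Dice agreement between two masks is 2|A∩B|/(|A|+|B|), with the both-empty
case pinned to 1.

## Synthetic phantoms and cohorts

Phantoms are background-intensity volumes (default level 200) containing
well-separated low-intensity components (default level 40): solid balls
(one H0 class each), solid tori (plus one H1), hollow spheres (plus one
H2; the interior stays at background so the cavity fills only late), and
hollow tori (one H2 plus two H1).  Shapes are Euclidean distance bands on
the voxel lattice; shells use bands of width 1.5 voxels, which cannot be
crossed by a 6-connected background path (distance to a center changes by
at most 1 per step), so cavities are watertight by construction.
Placement draws random centers and rejects any candidate whose solid hull
(cavity interiors included) comes within 2 voxels, in Chebyshev distance,
of an already-placed hull; generation is a pure function of the seed and
volumes are quantized to the integer 0–255 scale after adding Gaussian
noise.

The default two-class cohort — the condition used for the package's
parameter-recovery validation — has 80 samples per class on 32³ grids with
noise SD 4: both classes draw 1–3 blobs and 0–1 rings, and the positive
class additionally draws 3–5 hollow shells.  The class signal is therefore
purely topological (cavity content), not first-order intensity, which
makes H2-sensitive features the discriminative ones by construction and
gives the attribution analysis a testable expected outcome.  Covariate
tables (age, sex, location, consistency, log-normal tumor volume, edema
index (Vt+Ve)/Vt with a class-shifted edema volume and a point mass at
zero edema, extent of resection) are drawn with the marginal structure of
a meningioma surgical cohort of 161 patients with a 49% event rate.

What the phantoms do **not** emulate: MRI physics (partial-volume effects,
bias fields, scanner noise spectra), anatomically realistic ROI shapes, or
correlated intensity texture.  Passing tests therefore demonstrate that
the pipeline recovers topological class signal under controlled
conditions, not clinical-grade performance on real MRI.

## Prediction pipeline

Nested stratified CV, 5 outer × 3 inner folds, stratified on the binary
label.  Per outer fold, fitted on training rows only and in this order:
missingness filter (> 30%), median imputation, constant/low-variance
filter (< 0.001, measured on imputed training values), z-scoring; applying
a fitted state never refits.  Feature selection is L1-penalized logistic
regression (liblinear) with the inverse strength C searched over a
50-point log grid from 0.01 to 10 by mean inner-CV AUC, using the
**one-standard-error rule** (strongest penalty within one SE of the best),
which keeps pure-noise inputs sparse; the selection is the nonzero-
coefficient set after refitting on the full outer-training split.  If the
selection is empty the fold carries all preprocessed features forward so
it still produces scores.  Classifier adapters (fit/predict_proba) wrap a
built-in L2 logistic regression (default) plus random forest, SVM, MLP,
XGBoost and TabPFN when installed; external classifiers are called, never
re-implemented.

Metrics: AUC as the tie-corrected Mann–Whitney statistic;
accuracy/sensitivity/specificity at the Youden-J threshold chosen on
outer-training scores (the classification threshold rule is otherwise
unspecified, and Youden-J yields the near-balanced sensitivity/specificity
this design targets); 95% CI across folds by the normal approximation
(mean ± 1.96·SE of the 5 fold AUCs); DeLong's structural-components test
on pooled out-of-fold scores with identical-score input pinned to
(z, p) = (0, 1); calibration as observed event rate per equal-width score
bin; net benefit NB(pt) = TP/N − (FP/N)·pt/(1−pt) with treat-all
prev − (1−prev)·pt/(1−pt).  Family stability collapses per-fold selections
to families and reports mean pairwise Jaccard (both-empty pairs count 1),
per-family selection frequency, mean set size, and the families selected
in every fold.

## Clinical statistics

Pearson chi-square without continuity correction (this is the variant that
reproduces the reference cohort's printed categorical p-values; the Yates
correction does not), Fisher's exact test for 2×2 tables whenever any
expected count is below 5, Welch's t-test for normal continuous variables
and the Mann–Whitney U (tie-corrected normal approximation, no continuity
correction) otherwise, routed by Shapiro–Wilk at α = 0.05.  Fisher,
Mann–Whitney, t and Shapiro–Wilk delegate to scipy.stats as declared thin
wrappers; the chi-square is the explicit Σ(O−E)²/E formula.  The edema
index is (V_tumor + V_edema)/V_tumor, defined for positive tumor volume.

## Shapley attribution

Permutation-sampling estimate on the predicted-probability scale: for each
explained row, random feature orderings are walked from a background row
to the explained row, accumulating marginal prediction changes; absent
features take values from the background (the fold's preprocessed training
rows — an explicit choice, since the reference background is otherwise
unspecified).  Background rows are cycled deterministically rather than
resampled, which removes one Monte-Carlo variance component and makes the
estimator exact for additive models up to the cycling remainder; 500
permutations per sample by default (200 in the batch experiments, enough
for top-10 rankings).  The base value is the mean background prediction,
so efficiency (base + Σφ ≈ prediction) holds within MC tolerance; dummy
and symmetry axioms are verified in the tests.  Fold-wise attributions are
pooled for global importance (mean |φ|), and top-10 features per fold are
aggregated into homology-dimension and descriptor-family percentage
breakdowns.

## Problem sizes and determinism

The validation experiments use 160-sample cohorts of 32³ volumes
(~90 s end-to-end on one core), 16³ phantoms for known-topology checks,
and exhaustive small-grid oracle comparisons (3×3 binary, 4³ random).
Every stochastic step — phantom placement, noise, fold splitting, LASSO
and classifier seeds, Shapley permutations — is driven by explicit integer
seeds; two runs with the same seed produce identical serialized results.

## Design notes and limitations

* The package is a library-first artifact: the public surface is the
  importable API plus the `examples/` scripts; no console entry points are
  installed, and simulation/training/statistics/attribution are invoked as
  functions.
* DeLong comparisons assume paired scores on identical samples; the CI
  across 5 fold AUCs relies on a normal approximation that is crude for
  5 values and is reported as such.
* The cubical reduction stores full reduced columns; worst-case memory is
  quadratic, though image filtrations in practice stay near-linear.
  Volumes around 64³ are comfortable; substantially larger ROIs should be
  cropped (`crop_to_roi`) first.
* The GF(2)-rank oracle is exponential-ish in cell count and intended for
  grids up to ~20³; it exists for validation, not production use.
* TabPFN support is an optional adapter; when the package is not
  installed, requesting it raises a configuration error rather than
  silently substituting another model.
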