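# topovox

Topological characterization of voxel ROIs for outcome prediction:
sublevel-set **cubical persistent homology** on masked 3D image volumes, a
fixed **717-feature** persistence-diagram vectorization, a **nested
cross-validated LASSO + classifier** pipeline with discrimination /
calibration / decision-curve evaluation, clinical cohort-comparison
statistics, and Monte-Carlo **Shapley** feature attribution.

## The problem

Postoperative hemorrhage and edema enlargement is a serious complication of
brain-tumor resection, and the peritumoral edema (PE) region visible on
preoperative MRI carries information about that risk.  Conventional
radiomics summarizes the ROI's intensity distribution and texture;
topological data analysis instead characterizes its **multiscale spatial
organization**: how intensity sublevel sets fragment into components (H0),
form loops (H1), and enclose cavities (H2) as an activation threshold
sweeps the intensity range.

Concretely, an ROI-masked volume with intensities normalized to [0, 255]
defines a cubical complex in which each voxel is a cube with its faces,
edges and vertices (lower cells valued by the minimum incident voxel).
Activating cells with value ≤ t as t grows yields a filtration; persistent
homology records each topological class as a (birth, death) pair, and the
resulting diagrams are vectorized into seven descriptor families (summary
statistics, persistence entropy, Betti curves, persistence landscapes,
amplitude metrics, persistence images, heat-kernel signatures) per homology
dimension — 239 × 3 = **717 named features** per ROI.

Downstream, models are developed inside a nested stratified cross-validation
design (5 outer × 3 inner folds): preprocessing (missingness filter, median
imputation, variance filter, z-scoring) and L1-logistic feature selection
are fitted on outer-training data only, a classifier is refit on the
selection and scored out-of-fold.  Evaluation covers AUC with fold-level
95% CI, accuracy/sensitivity/specificity at the Youden threshold, DeLong
tests between models, calibration curves, decision-curve net benefit
NB(pt) = TP/N − (FP/N)·pt/(1−pt), family-level selection stability
(mean pairwise Jaccard), and permutation-sampling Shapley attribution on
the predicted-probability scale.

Since clinical imaging cohorts are rarely releasable, the package ships a
first-class synthetic-cohort module: 3D phantoms whose blob/ring/shell
content fixes the ground-truth Betti numbers, so the entire chain — from
filtration to attribution — is validated against known topology.

## Worked example

```python
import topovox as tv

grid, expected = tv.make_phantom(
    tv.PhantomSpec(shape=(16, 16, 16), n_blobs=0, n_hollow_tori=1, seed=5))
diagram = tv.roi_diagram(grid)          # filtration + persistence
print(expected, diagram.betti_at(100))  # -> (1, 2, 1) (1, 2, 1)

vec = tv.roi_feature_vector(grid)       # the 717-feature vector
print(vec.values.size)                  # -> 717
```

A hollow torus is one connected component carrying two independent loops
and one enclosed cavity — the measured Betti numbers at mid-filtration
`(1, 2, 1)` recover exactly that.  Running the cohort example
(`python examples/04_cohort_prediction.py`, 50 samples whose positive class
carries 1–2 extra cavities) prints per-fold validation AUCs of 1.0, a mean
family-level Jaccard of 0.867, and `['amp_bottleneck_d2', 'land_d2_l0']` as
the families selected in every fold — the cavity-sensitive H2 descriptors,
exactly the families that carry the injected class signal.

The `examples/` directory has one short script per capability: the worked
2D filtration, phantom topology recovery, feature extraction, nested-CV
prediction, Shapley attribution, and the clinical comparison table.

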