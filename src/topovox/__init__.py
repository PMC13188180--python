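"""topovox: topological feature extraction and prediction from voxel ROIs.

Sublevel-set cubical persistent homology on (masked) image volumes, a fixed
717-feature diagram vectorization, synthetic phantom cohorts with known
topology, a nested cross-validated LASSO + classifier pipeline with
discrimination/calibration/decision-curve evaluation, clinical
cohort-comparison statistics, and Monte-Carlo Shapley attribution.
"""

from . import clinstats, features, persistence, pipeline, preprocess, shapley, synthetic
from .features import TopoFeatureVector, VectorizerConfig, assemble_features, feature_names
from .persistence import (
    FiltrationComplex,
    PersistenceDiagram,
    PersistencePair,
    betti_at_threshold,
    build_filtration,
    compute_persistence,
    euler_curve,
)
from .preprocess import (
    DegenerateROIError,
    VoxelGrid,
    crop_to_roi,
    dice_coefficient,
    load_volume,
    normalize_roi,
    resample_isotropic,
    save_volume,
)
from .synthetic import CohortSpec, PhantomSpec, make_phantom, simulate_cohort

__version__ = "0.1.0"


def roi_diagram(grid) -> PersistenceDiagram:
    """Filtration + persistence of one (masked) voxel grid."""
    return compute_persistence(build_filtration(grid))


def roi_feature_vector(grid, config: VectorizerConfig = None) -> TopoFeatureVector:
    """End-to-end: grid -> diagram -> 717-feature vector."""
    cfg = config or features.DEFAULT_CONFIG
    return assemble_features(roi_diagram(grid), cfg)
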