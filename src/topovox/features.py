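"""Fixed 717-dimensional vectorization of persistence diagrams.

Seven descriptor families are computed per homology dimension (H0, H1, H2):

==============  ====  =========================================================
family          size  content
==============  ====  =========================================================
stats             15  point count; lifetime sum/mean/std/median/min/max;
                      birth mean/std/min/max; death mean/std/min/max
entropy            1  persistence entropy −Σ (l_i/L) ln(l_i/L)
betti             30  Betti curve sampled at 30 bin centers of [0, 255]
landscape        150  persistence landscape, 3 layers × 50 bins
amplitude          3  bottleneck / Wasserstein-2 / landscape distance to the
                      empty diagram
image             20  persistence image (20×20, σ=1.0, linear weighting):
                      mean/std/max/sum + 16 mean-pooled 5×5 blocks
heat              20  signed heat-kernel field (20×20, σ=1.0), same summaries
==============  ====  =========================================================

15+1+30+150+3+20+20 = 239 per dimension, 717 over the three dimensions.  All
samplings use the fixed global range [0, 255] so vectors are comparable
across subjects after ROI normalization.  Conventions pinned here: population
(n-denominator) standard deviations, natural-log entropy, half-open [b, d)
Betti activity, mean block pooling in row-major block order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_FEATURES = 717
_STAT_NAMES = [
    "n_points", "life_sum", "life_mean", "life_std", "life_median",
    "life_min", "life_max", "birth_mean", "birth_std", "birth_min",
    "birth_max", "death_mean", "death_std", "death_min", "death_max",
]


@dataclass(frozen=True)
class VectorizerConfig:
    filtration_range: tuple = (0.0, 255.0)
    landscape_layers: int = 3
    landscape_bins: int = 50
    betti_bins: int = 30
    image_grid: tuple = (20, 20)
    image_sigma: float = 1.0       # in intensity units of the filtration scale
    blocks: tuple = (4, 4)

    @property
    def per_dim_budget(self) -> int:
        n_img = 4 + self.blocks[0] * self.blocks[1]
        return (len(_STAT_NAMES) + 1 + self.betti_bins
                + self.landscape_layers * self.landscape_bins + 3 + 2 * n_img)


DEFAULT_CONFIG = VectorizerConfig()


@dataclass
class TopoFeatureVector:
    """Ordered, named feature vector for one ROI (length 717 by default)."""

    values: np.ndarray
    names: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError("values/names length mismatch")

    @property
    def families(self) -> list:
        return [feature_family(n) for n in self.names]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def feature_family(name: str) -> str:
    """Collapse a feature name to its family by stripping bin/block indices.

    ``landscape_d1_l2_b30`` → ``land_d1_l2``; ``betti_d0_b12`` → ``betti_d0``;
    ``pi_blk2_3_d0`` → ``pi_d0``; scalar features are their own family
    (``life_std_d2`` → ``life_std_d2``).
    """
    if name.startswith("landscape_"):
        return "land_" + "_".join(name.split("_")[1:3])
    if name.startswith("betti_") and "_b" in name[6:]:
        return name.rsplit("_b", 1)[0]
    for pref in ("pi_blk", "hk_blk"):
        if name.startswith(pref):
            return name[:2] + "_" + name.rsplit("_", 1)[1]
    return name


def feature_names(config: VectorizerConfig = DEFAULT_CONFIG) -> list:
    """The fixed, ordered names of the full feature vector."""
    names = []
    for d in range(3):
        names += [f"{s}_d{d}" for s in _STAT_NAMES]
        names.append(f"entropy_d{d}")
        names += [f"betti_d{d}_b{i}" for i in range(config.betti_bins)]
        names += [
            f"landscape_d{d}_l{layer}_b{i}"
            for layer in range(config.landscape_layers)
            for i in range(config.landscape_bins)
        ]
        names += [f"amp_{m}_d{d}" for m in ("bottleneck", "wasserstein", "landscape")]
        for pref in ("pi", "hk"):
            names += [f"{pref}_{s}_d{d}" for s in ("mean", "std", "max", "sum")]
            names += [
                f"{pref}_blk{r}_{c}_d{d}"
                for r in range(config.blocks[0])
                for c in range(config.blocks[1])
            ]
    return names


def _bin_centers(lo, hi, n):
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _pairs(diagram, dim) -> np.ndarray:
    if hasattr(diagram, "by_dim"):
        pts = diagram.by_dim(dim)
    else:
        pts = np.asarray(diagram, dtype=float).reshape(-1, 2)
    if pts.shape[0] > 1:
        # canonical point order: makes every vectorizer bit-reproducible
        # under permutation of the diagram's multiset of points
        pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    return pts


def diagram_stats(diagram, dim, config=DEFAULT_CONFIG) -> np.ndarray:
    """15 summary statistics of the (birth, death, lifetime) distributions.

    Empty diagrams yield all zeros; standard deviations use the population
    (n) denominator, so a single point has std 0.
    """
    pts = _pairs(diagram, dim)
    if pts.shape[0] == 0:
        return np.zeros(len(_STAT_NAMES))
    b, d = pts[:, 0], pts[:, 1]
    life = d - b
    return np.array([
        pts.shape[0], life.sum(), life.mean(), life.std(), np.median(life),
        life.min(), life.max(), b.mean(), b.std(), b.min(), b.max(),
        d.mean(), d.std(), d.min(), d.max(),
    ])


def persistence_entropy(diagram, dim, config=DEFAULT_CONFIG) -> float:
    """Shannon entropy of the normalized lifetime distribution (natural log)."""
    pts = _pairs(diagram, dim)
    life = pts[:, 1] - pts[:, 0] if pts.size else np.empty(0)
    total = life.sum()
    if total <= 0:
        return 0.0
    p = life[life > 0] / total
    return float(-(p * np.log(p)).sum())


def betti_curve(diagram, dim, config=DEFAULT_CONFIG) -> np.ndarray:
    """Number of classes alive (birth <= t < death) at each of 30 bin centers."""
    pts = _pairs(diagram, dim)
    t = _bin_centers(*config.filtration_range, config.betti_bins)
    if pts.shape[0] == 0:
        return np.zeros(t.size)
    alive = (pts[:, :1] <= t) & (t < pts[:, 1:2])
    return alive.sum(axis=0).astype(float)


def persistence_landscape(diagram, dim, config=DEFAULT_CONFIG) -> np.ndarray:
    """Persistence landscape λ_1..λ_K sampled at bin centers, flattened
    layer-major to K×bins values.

    λ_k(t) is the k-th largest tent value max(0, min(t−b_i, d_i−t)); layers
    beyond the number of points are zero.
    """
    pts = _pairs(diagram, dim)
    t = _bin_centers(*config.filtration_range, config.landscape_bins)
    K = config.landscape_layers
    out = np.zeros((K, t.size))
    if pts.shape[0]:
        tents = np.maximum(
            0.0, np.minimum(t - pts[:, :1], pts[:, 1:2] - t)
        )  # (n_pairs, bins)
        k = min(K, tents.shape[0])
        top = -np.sort(-tents, axis=0)[:k]
        out[:k] = top
    return out.ravel()


def amplitudes(diagram, dim, config=DEFAULT_CONFIG) -> np.ndarray:
    """Bottleneck, Wasserstein-2 and landscape distances to the empty diagram.

    For a diagram with lifetimes l_i these reduce to max(l)/2, ‖l‖₂/√2 and
    the bin-width-scaled L2 norm of the discretized landscape.
    """
    pts = _pairs(diagram, dim)
    if pts.shape[0] == 0:
        return np.zeros(3)
    life = pts[:, 1] - pts[:, 0]
    bottleneck = life.max() / 2.0
    wasserstein = float(np.linalg.norm(life / np.sqrt(2.0)))
    lam = persistence_landscape(diagram, dim, config)
    lo, hi = config.filtration_range
    dt = (hi - lo) / config.landscape_bins
    landscape_amp = float(np.sqrt((lam ** 2).sum() * dt))
    return np.array([bottleneck, wasserstein, landscape_amp])


def _grid_field_summaries(field2d, config) -> np.ndarray:
    """mean/std/max/sum + row-major mean-pooled blocks of a 20×20 field."""
    br, bc = config.blocks
    g = field2d
    stats = [g.mean(), g.std(), g.max(), g.sum()]
    rs, cs = g.shape[0] // br, g.shape[1] // bc
    blocks = g.reshape(br, rs, bc, cs).mean(axis=(1, 3))
    return np.concatenate([stats, blocks.ravel()])


def _gauss2d(xc, yc, px, py, sigma):
    # normalized 2D Gaussian evaluated at grid centers, one point per row
    dx = xc[None, :] - px[:, None]
    dy = yc[None, :] - py[:, None]
    norm = 1.0 / (2.0 * np.pi * sigma ** 2)
    return norm * np.exp(-(dx[:, :, None] ** 2 + dy[:, None, :] ** 2)
                         / (2.0 * sigma ** 2))


def persistence_image(diagram, dim, config=DEFAULT_CONFIG) -> np.ndarray:
    """Persistence image on the (birth, persistence) plane: Gaussian kernel
    σ=1.0, linear persistence weighting, 20×20 grid over [0,255]², summarized
    by 4 global statistics and 16 mean-pooled blocks (20 values)."""
    pts = _pairs(diagram, dim)
    gr, gc = config.image_grid
    if pts.shape[0] == 0:
        return np.zeros(4 + config.blocks[0] * config.blocks[1])
    lo, hi = config.filtration_range
    xc = _bin_centers(lo, hi, gr)   # birth axis
    yc = _bin_centers(lo, hi, gc)   # persistence axis
    b = pts[:, 0]
    p = pts[:, 1] - pts[:, 0]
    k = _gauss2d(xc, yc, b, p, config.image_sigma)      # (n, gr, gc)
    field = (p[:, None, None] * k).sum(axis=0)
    return _grid_field_summaries(field, config)


def heat_kernel(diagram, dim, config=DEFAULT_CONFIG) -> np.ndarray:
    """Signed heat-kernel signature: Gaussian mass at each diagram point minus
    its diagonal mirror, on a 20×20 grid over [0,255]², same summaries."""
    pts = _pairs(diagram, dim)
    gr, gc = config.image_grid
    if pts.shape[0] == 0:
        return np.zeros(4 + config.blocks[0] * config.blocks[1])
    lo, hi = config.filtration_range
    xc = _bin_centers(lo, hi, gr)
    yc = _bin_centers(lo, hi, gc)
    k_pt = _gauss2d(xc, yc, pts[:, 0], pts[:, 1], config.image_sigma)
    k_mir = _gauss2d(xc, yc, pts[:, 1], pts[:, 0], config.image_sigma)
    field = (k_pt - k_mir).sum(axis=0)
    return _grid_field_summaries(field, config)


_FAMILY_FUNCS = (
    diagram_stats,
    lambda D, d, c: np.atleast_1d(persistence_entropy(D, d, c)),
    betti_curve,
    persistence_landscape,
    amplitudes,
    persistence_image,
    heat_kernel,
)


def assemble_features(diagram, config: VectorizerConfig = DEFAULT_CONFIG) -> TopoFeatureVector:
    """Concatenate all families over homology dimensions 0, 1, 2.

    Output order per dimension: stats, entropy, Betti curve, landscape,
    amplitudes, persistence image, heat kernel; length 717 with the default
    configuration.  Invariant to the ordering of diagram points.
    """
    parts = []
    for d in range(3):
        for fn in _FAMILY_FUNCS:
            parts.append(np.atleast_1d(fn(diagram, d, config)))
    values = np.concatenate(parts)
    names = feature_names(config)
    if values.size != len(names):
        raise AssertionError("feature budget mismatch")
    return TopoFeatureVector(values=values, names=names)


def feature_table(diagrams: dict, config: VectorizerConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Vectorize a {sample_id: diagram} mapping into a samples × 717 table."""
    rows = {sid: assemble_features(D, config).values for sid, D in diagrams.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=feature_names(config))


def group_mean_landscape(table: pd.DataFrame, labels, dim: int,
                         config: VectorizerConfig = DEFAULT_CONFIG) -> dict:
    """Per-group mean landscape curves, shape (layers, bins) per group.

    By linearity of the landscape features this equals the landscape of the
    group-mean feature vector restricted to the landscape block.
    """
    labels = pd.Series(np.asarray(labels), index=table.index)
    cols = [
        f"landscape_d{dim}_l{layer}_b{i}"
        for layer in range(config.landscape_layers)
        for i in range(config.landscape_bins)
    ]
    out = {}
    for g, sub in table.groupby(labels):
        out[g] = sub[cols].mean(axis=0).to_numpy().reshape(
            config.landscape_layers, config.landscape_bins
        )
    return out
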