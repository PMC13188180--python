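"""Monte-Carlo (permutation-sampling) Shapley attribution for fold models.

For a predict-probability function f, explained row x and background
reference set Z, the Shapley value of feature j is estimated by averaging
marginal contributions f(S ∪ {j}) − f(S) over random feature orderings,
with features absent from the coalition replaced by values from a randomly
drawn background row.  Attributions live on the predicted-probability
scale; the base value is the mean background prediction, so for each sample
base + Σ_j φ_j ≈ f(x) up to Monte-Carlo error (the efficiency axiom).

Fold-wise aggregation, global importance ranking (mean |φ|), and
homology-dimension / descriptor-family breakdowns of top-ranked features
mirror how attribution is summarized for nested-CV models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import feature_family


class NamingError(ValueError):
    """Feature name does not follow the <family>_d<dim>[_...] scheme."""


@dataclass
class ShapleyAttribution:
    """Per-sample × per-feature attributions on the probability scale."""

    values: pd.DataFrame          # rows = samples, cols = features
    base_value: float
    n_permutations: int
    seed: int

    def efficiency_gap(self, predictions) -> np.ndarray:
        """base + Σφ − f(x) per sample (should be ~0 within MC tolerance)."""
        return self.base_value + self.values.sum(axis=1).to_numpy() \
            - np.asarray(predictions, dtype=float)


def _predict(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return np.asarray(model(X), dtype=float).ravel()


def shapley_sampling(model, X: pd.DataFrame, background: pd.DataFrame,
                     n_permutations: int = 500, seed: int = 0) -> ShapleyAttribution:
    """Permutation-sampling Shapley estimate for each row of ``X``.

    ``model`` is either an object with ``predict_proba`` or a callable
    returning scores.  ``background`` provides the replacement distribution
    for absent features (typically the fold's preprocessed training rows).
    Deterministic given ``seed``.
    """
    if list(X.columns) != list(background.columns):
        raise ValueError("X and background must share the same feature space")
    rng = np.random.default_rng(seed)
    Xa = np.asarray(X, dtype=float)
    Z = np.asarray(background, dtype=float)
    n, d = Xa.shape
    phi = np.zeros((n, d))
    base = float(_predict(model, Z).mean())
    for i in range(n):
        x = Xa[i]
        # one batched model call per sample: n_permutations chains of d+1 points
        batch = np.empty((n_permutations, d + 1, d))
        orders = np.empty((n_permutations, d), dtype=np.int64)
        for p in range(n_permutations):
            order = rng.permutation(d)
            # cycle through background rows (instead of resampling) for
            # lower Monte-Carlo variance at fixed permutation count
            z = Z[p % Z.shape[0]]
            orders[p] = order
            cur = z.copy()
            batch[p, 0] = cur
            for step, j in enumerate(order):
                cur = cur.copy()
                cur[j] = x[j]
                batch[p, step + 1] = cur
        preds = _predict(model, batch.reshape(-1, d)).reshape(n_permutations, d + 1)
        deltas = np.diff(preds, axis=1)          # contribution at each step
        for p in range(n_permutations):
            phi[i, orders[p]] += deltas[p]
    phi /= n_permutations
    return ShapleyAttribution(
        values=pd.DataFrame(phi, index=X.index, columns=X.columns),
        base_value=base, n_permutations=n_permutations, seed=seed,
    )


def explain_cv(cv_result, table: pd.DataFrame, n_permutations: int = 500,
               seed: int = 0, feature_cols=None, label_col: str = "label") -> list:
    """Shapley attributions for each outer fold's validation rows.

    Uses the fold-specific preprocessing state and fitted model from a
    :class:`~topovox.pipeline.CVResult`; the background is the fold's
    preprocessed training rows.  Returns one ShapleyAttribution per fold.
    """
    from .pipeline import apply_preprocess

    if feature_cols is None:
        feature_cols = [c for c in table.columns if c != label_col
                        and pd.api.types.is_numeric_dtype(table[c])]
    X = table[feature_cols]
    out = []
    for f in cv_result.folds:
        val_idx = f.val_index
        train_idx = [i for i in X.index if i not in set(val_idx)]
        Xtr = apply_preprocess(f.state, X.loc[train_idx])[f.selected]
        Xva = apply_preprocess(f.state, X.loc[val_idx])[f.selected]
        out.append(shapley_sampling(f.model, Xva, Xtr,
                                    n_permutations=n_permutations,
                                    seed=seed + f.fold))
    return out


def aggregate_importance(attributions) -> dict:
    """Global importance from fold-wise attributions.

    Concatenates out-of-fold attribution rows (union of feature spaces),
    ranks features by mean absolute attribution, and prepares beeswarm-ready
    (long) and heatmap-ready (feature × sample, samples sorted by total
    attribution) tables.
    """
    frames = [a.values for a in attributions]
    combined = pd.concat(frames, axis=0)
    importance = combined.abs().mean(axis=0, skipna=True).sort_values(ascending=False)
    long = combined.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="feature", value_name="shap_value"
    ).dropna(subset=["shap_value"])
    order = combined.sum(axis=1).sort_values().index
    heatmap = combined.loc[order].T
    return {"importance": importance, "beeswarm": long, "heatmap": heatmap}


_DIM_RE = re.compile(r"_d([012])(_|$)")


def homology_dim_of(name: str) -> int:
    m = _DIM_RE.search(name)
    if not m:
        raise NamingError(f"cannot parse homology dimension from {name!r}")
    return int(m.group(1))


_FAMILY_TYPES = (
    ("landscape_", "landscape"), ("betti_", "betti"), ("amp_", "amplitude"),
    ("pi_", "image"), ("hk_", "heat"), ("entropy", "entropy"),
)


def family_type_of(name: str) -> str:
    for pref, fam in _FAMILY_TYPES:
        if name.startswith(pref):
            return fam
    if any(name.startswith(s) for s in ("n_points", "life_", "birth_", "death_")):
        return "stats"
    raise NamingError(f"cannot parse descriptor family from {name!r}")


def dimension_breakdown(top_features_per_fold, k: int = 10) -> dict:
    """Proportions of top-k features per homology dimension and family type.

    ``top_features_per_fold`` is an iterable of per-fold ranked feature
    lists; the first k of each fold are pooled.  Each grouping's
    percentages sum to 100.
    """
    pooled = []
    for feats in top_features_per_fold:
        pooled.extend(list(feats)[:k])
    if not pooled:
        raise ValueError("no features to aggregate")
    dims = pd.Series([f"H{homology_dim_of(f)}" for f in pooled])
    fams = pd.Series([family_type_of(f) for f in pooled])
    by_dim = (100 * dims.value_counts(normalize=True)).reindex(
        ["H0", "H1", "H2"], fill_value=0.0).to_dict()
    by_family = (100 * fams.value_counts(normalize=True)).to_dict()
    return {"by_dimension": by_dim, "by_family": by_family,
            "n_features": len(pooled)}


def top_features(attribution: ShapleyAttribution, k: int = 10) -> list:
    """Features ranked by mean |attribution| within one fold."""
    return list(attribution.values.abs().mean(axis=0)
                .sort_values(ascending=False).index[:k])
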