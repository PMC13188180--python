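"""Nested cross-validated modeling on feature tables.

The modeling currency is a samples × (features + label) DataFrame.  Model
development follows a nested stratified cross-validation design: a 5-fold
outer loop estimates generalization and a 3-fold inner loop drives LASSO
feature selection (and its regularization strength), with every
preprocessing statistic fitted on outer-training rows only so no
information leaks into the validation folds.  Preprocessing order:
missingness filter (>30%) → median imputation → constant/low-variance
filter (<0.001) → z-scoring.

Evaluation: AUC (Mann-Whitney with tie correction) with a 95% CI across
outer folds, accuracy/sensitivity/specificity at the Youden-J-optimal
threshold chosen on outer-training scores, DeLong's test for correlated
AUCs, calibration curves, decision-curve net benefit, and feature-family
selection stability (mean pairwise Jaccard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools
import json

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .features import feature_family

MISSING_FRAC = 0.30
VARIANCE_MIN = 1e-3


class ConfigurationError(ValueError):
    """Unknown classifier adapter or invalid run configuration."""


class MetricError(ValueError):
    """Raised when a metric is undefined (e.g. one-class input)."""


# ---------------------------------------------------------------------------
# Preprocessing

@dataclass
class PreprocessState:
    """Training-fitted preprocessing: kept columns, medians, z-score stats."""

    kept: list
    medians: pd.Series
    means: pd.Series
    sds: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        X = table[self.kept].copy()
        X = X.fillna(self.medians)
        return (X - self.means) / self.sds


def fit_preprocess(train: pd.DataFrame) -> PreprocessState:
    """Fit the preprocessing chain on training rows only.

    Filters in order: drop features missing in more than 30% of rows;
    median-impute the rest; drop constant and low-variance (<0.001)
    features (variance measured on imputed training values); z-score.
    """
    X = train.apply(pd.to_numeric, errors="coerce")
    keep = X.columns[X.isna().mean() <= MISSING_FRAC]
    X = X[keep]
    medians = X.median()
    X = X.fillna(medians)
    var = X.var(ddof=0)
    keep2 = X.columns[(var >= VARIANCE_MIN) & (var > 0)]
    if len(keep2) == 0:
        raise ValueError("all features filtered out during preprocessing")
    X = X[keep2]
    means = X.mean()
    sds = X.std(ddof=0)
    return PreprocessState(
        kept=list(keep2), medians=medians[keep2], means=means, sds=sds
    )


def apply_preprocess(state: PreprocessState, table: pd.DataFrame) -> pd.DataFrame:
    return state.apply(table)


# ---------------------------------------------------------------------------
# LASSO selection

def lasso_select(train: pd.DataFrame, labels, inner_folds: int = 3,
                 lambda_grid=None, seed: int = 0) -> list:
    """Features with nonzero L1-logistic coefficients at the inner-CV-chosen
    regularization strength.

    The inverse strength C is searched over a 50-point log grid (0.01-10 by
    default) by mean AUC over stratified inner folds, then the model is
    refit on the full training split at the winning C.
    """
    y = np.asarray(labels).astype(int)
    X = np.asarray(train, dtype=float)
    if lambda_grid is None:
        Cs = np.logspace(-2, 1, 50)
    else:
        Cs = 1.0 / np.asarray(lambda_grid, dtype=float)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for tr, _ in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate inner fold: one class only")
    mean_auc = np.zeros(Cs.size)
    se_auc = np.zeros(Cs.size)
    for ci, C in enumerate(Cs):
        aucs = []
        for tr, va in folds:
            clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                     max_iter=2000, random_state=seed)
            clf.fit(X[tr], y[tr])
            s = clf.decision_function(X[va])
            if len(np.unique(y[va])) < 2:
                continue
            aucs.append(roc_auc(s, y[va]))
        mean_auc[ci] = np.mean(aucs) if aucs else 0.5
        se_auc[ci] = (np.std(aucs, ddof=1) / np.sqrt(len(aucs))
                      if len(aucs) > 1 else 0.0)
    # one-standard-error rule: strongest penalty whose inner-CV AUC is
    # within one SE of the best, so pure-noise inputs stay sparse
    best = int(np.argmax(mean_auc))
    cutoff = mean_auc[best] - se_auc[best]
    best = int(np.flatnonzero(mean_auc >= cutoff)[0])  # Cs ascending: smallest C
    clf = LogisticRegression(l1_ratio=1.0, C=Cs[best], solver="liblinear",
                             max_iter=2000, random_state=seed)
    clf.fit(X, y)
    nz = np.flatnonzero(np.abs(clf.coef_.ravel()) > 0)
    return [train.columns[i] for i in nz]


# ---------------------------------------------------------------------------
# Classifier adapters

def get_classifier(name: str, seed: int = 0):
    """Instantiate a classifier adapter exposing fit / predict_proba.

    Built-in default is a regularized logistic regression; the other names
    delegate to established implementations and are called, not
    re-implemented.
    """
    name = name.lower()
    if name in ("logistic", "lr"):
        return LogisticRegression(C=1.0, max_iter=5000, random_state=seed)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(n_estimators=300, random_state=seed)
    if name == "svm":
        from sklearn.svm import SVC
        return SVC(probability=True, random_state=seed)
    if name == "mlp":
        from sklearn.neural_network import MLPClassifier
        return MLPClassifier(hidden_layer_sizes=(64,), max_iter=2000,
                             early_stopping=True, random_state=seed)
    if name == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as e:
            raise ConfigurationError("xgboost is not installed") from e
        return XGBClassifier(n_estimators=200, max_depth=3, learning_rate=0.05,
                             random_state=seed)
    if name == "tabpfn":
        try:
            from tabpfn import TabPFNClassifier
        except ImportError as e:
            raise ConfigurationError(
                "tabpfn is not installed; install it or use another adapter"
            ) from e
        return TabPFNClassifier()
    raise ConfigurationError(f"unknown classifier adapter: {name!r}")


# ---------------------------------------------------------------------------
# Metrics

def roc_auc(scores, labels) -> float:
    """AUC as the tie-corrected Mann-Whitney statistic U / (n0 · n1)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise MetricError("AUC undefined with a single class")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity − 1 over unique scores."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    best_t, best_j = 0.5, -np.inf
    for t in np.unique(s):
        pred = s >= t
        sens = (pred & (y == 1)).sum() / max(1, (y == 1).sum())
        spec = (~pred & (y == 0)).sum() / max(1, (y == 0).sum())
        j = sens + spec - 1
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def threshold_metrics(scores, labels, threshold) -> tuple:
    """(accuracy, sensitivity, specificity) for predictions score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise MetricError("metrics undefined with a single class")
    pred = (s >= threshold).astype(int)
    acc = float((pred == y).mean())
    sens = float(pred[y == 1].mean())
    spec = float(1 - pred[y == 0].mean())
    return acc, sens, spec


def _delong_components(scores, labels):
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    # psi(x, y) = 1 if x > y, 0.5 if equal, else 0
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    auc = psi.mean()
    v10 = psi.mean(axis=1)   # per positive
    v01 = psi.mean(axis=0)   # per negative
    return auc, v10, v01


def delong_compare(scores_a, scores_b, labels) -> tuple:
    """DeLong's test for two correlated AUCs on paired scores.

    Returns (auc_a, auc_b, z, p) with the structural-components covariance
    and a two-sided normal p-value; identical scores give z = 0, p = 1.
    """
    sa, sb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if sa.shape != sb.shape:
        raise ValueError("paired score vectors must have equal length")
    auc_a, v10a, v01a = _delong_components(sa, labels)
    auc_b, v10b, v01b = _delong_components(sb, labels)
    n1, n0 = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    diff = auc_a - auc_b
    if var <= 0 or diff == 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


def delong_variance(scores, labels) -> float:
    """Single-model DeLong variance of the AUC (structural components)."""
    auc, v10, v01 = _delong_components(scores, labels)
    n1, n0 = v10.size, v01.size
    return float(np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0)


def auc_ci(fold_aucs, level: float = 0.95) -> tuple:
    """(mean, lo, hi): normal-approximation CI across outer-fold AUCs."""
    a = np.asarray(fold_aucs, dtype=float)
    m = a.mean()
    se = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0
    zq = sps.norm.ppf(0.5 + level / 2)
    return float(m), float(m - zq * se), float(m + zq * se)


def calibration_curve(scores, labels, bins: int = 10) -> pd.DataFrame:
    """Observed event rate vs mean predicted score per equal-width bin."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    edges = np.linspace(0, 1, bins + 1)
    idx = np.clip(np.digitize(s, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        m = idx == b
        if m.any():
            rows.append({"bin": b, "mean_score": s[m].mean(),
                         "event_rate": y[m].mean(), "n": int(m.sum())})
    return pd.DataFrame(rows)


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    model: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "net_benefit_model": self.model,
            "net_benefit_all": self.treat_all, "net_benefit_none": self.treat_none,
        })


def decision_curve(scores, labels, thresholds=None) -> NetBenefitCurve:
    """Decision-curve analysis: NB(pt) = TP/N − (FP/N)·pt/(1−pt).

    Predictions are positive iff score >= pt.  Treat-all equals
    prev − (1−prev)·pt/(1−pt); treat-none is identically zero.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    n = y.size
    prev = y.mean()
    nb_model = np.empty(thresholds.size)
    for i, pt in enumerate(thresholds):
        pred = s >= pt
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb_model[i] = tp - fp * pt / (1 - pt)
    nb_all = prev - (1 - prev) * thresholds / (1 - thresholds)
    return NetBenefitCurve(thresholds, nb_model, nb_all, np.zeros_like(thresholds))


# ---------------------------------------------------------------------------
# Nested cross-validation

@dataclass
class FoldResult:
    fold: int
    selected: list
    train_auc: float
    val_auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    val_index: list
    state: PreprocessState = field(repr=False, default=None)
    model: object = field(repr=False, default=None)


@dataclass
class CVResult:
    """Per-fold selections and metrics plus pooled out-of-fold scores."""

    folds: list
    oof_scores: pd.Series
    labels: pd.Series
    classifier: str
    seed: int

    def fold_aucs(self, split: str = "val") -> list:
        key = "val_auc" if split == "val" else "train_auc"
        return [getattr(f, key) for f in self.folds]

    def summary(self) -> dict:
        mean, lo, hi = auc_ci(self.fold_aucs("val"))
        tmean, tlo, thi = auc_ci(self.fold_aucs("train"))
        return {
            "classifier": self.classifier,
            "val_auc_mean": mean, "val_auc_ci": [lo, hi],
            "train_auc_mean": tmean, "train_auc_ci": [tlo, thi],
            "accuracy_mean": float(np.mean([f.accuracy for f in self.folds])),
            "sensitivity_mean": float(np.mean([f.sensitivity for f in self.folds])),
            "specificity_mean": float(np.mean([f.specificity for f in self.folds])),
            "pooled_oof_auc": roc_auc(self.oof_scores.to_numpy(),
                                      self.labels.loc[self.oof_scores.index].to_numpy()),
        }

    def selected_sets(self) -> list:
        return [set(f.selected) for f in self.folds]

    def to_json(self, path=None):
        obj = {
            "classifier": self.classifier, "seed": self.seed,
            "summary": self.summary(),
            "folds": [
                {"fold": f.fold, "selected": sorted(f.selected),
                 "train_auc": f.train_auc, "val_auc": f.val_auc,
                 "accuracy": f.accuracy, "sensitivity": f.sensitivity,
                 "specificity": f.specificity, "threshold": f.threshold}
                for f in self.folds
            ],
            "oof_scores": {k: float(v) for k, v in self.oof_scores.items()},
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def nested_cv(table: pd.DataFrame, classifier: str = "logistic",
              outer: int = 5, inner: int = 3, seed: int = 0,
              label_col: str = "label", feature_cols=None) -> CVResult:
    """Nested stratified CV: preprocessing + LASSO selection fitted per outer
    training split, classifier refit on the outer-train selection, scored on
    the held-out outer fold.

    Stratification is on the binary label.  If LASSO selects nothing in a
    fold, all preprocessed features are carried forward (pinned fallback so
    the fold still produces scores).  Fully deterministic given ``seed``.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c != label_col
                        and pd.api.types.is_numeric_dtype(table[c])]
    y = table[label_col].astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("label must be binary 0/1")
    X = table[feature_cols]
    skf = StratifiedKFold(n_splits=outer, shuffle=True, random_state=seed)
    folds = []
    oof = {}
    for k, (tr, va) in enumerate(skf.split(X, y)):
        Xtr_raw, Xva_raw = X.iloc[tr], X.iloc[va]
        ytr, yva = y.iloc[tr], y.iloc[va]
        state = fit_preprocess(Xtr_raw)
        Xtr = apply_preprocess(state, Xtr_raw)
        Xva = apply_preprocess(state, Xva_raw)
        selected = lasso_select(Xtr, ytr, inner_folds=inner, seed=seed + k)
        if not selected:
            selected = list(Xtr.columns)
        model = get_classifier(classifier, seed=seed + k)
        model.fit(Xtr[selected].to_numpy(), ytr.to_numpy())
        p_tr = model.predict_proba(Xtr[selected].to_numpy())[:, 1]
        p_va = model.predict_proba(Xva[selected].to_numpy())[:, 1]
        thr = youden_threshold(p_tr, ytr)
        acc, sens, spec = threshold_metrics(p_va, yva, thr)
        folds.append(FoldResult(
            fold=k, selected=selected,
            train_auc=roc_auc(p_tr, ytr), val_auc=roc_auc(p_va, yva),
            accuracy=acc, sensitivity=sens, specificity=spec, threshold=thr,
            val_index=list(X.index[va]), state=state, model=model,
        ))
        for sid, sc in zip(X.index[va], p_va):
            oof[sid] = float(sc)
    oof_scores = pd.Series(oof).loc[X.index]
    return CVResult(folds=folds, oof_scores=oof_scores, labels=y,
                    classifier=classifier, seed=seed)


def load_run_config(path) -> dict:
    """Read a YAML run configuration into ``nested_cv`` keyword arguments.

    Recognized keys: classifier, outer, inner, seed, label_col; unknown keys
    are rejected so typos fail loudly.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = {"classifier", "outer", "inner", "seed", "label_col"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigurationError(f"unknown run-config keys: {sorted(unknown)}")
    return cfg


# ---------------------------------------------------------------------------
# Feature-family stability

def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def family_stability(selected_sets) -> dict:
    """Family-level selection stability across outer folds.

    Feature names are collapsed to families (bin/block indices stripped);
    reported are the mean pairwise Jaccard similarity of the per-fold family
    sets, each family's selection frequency, the mean family-set size, and
    the families selected in every fold.
    """
    fam_sets = [set(feature_family(f) for f in s) for s in selected_sets]
    if len(fam_sets) < 2:
        raise ValueError("need at least two folds")
    pairs = list(itertools.combinations(range(len(fam_sets)), 2))
    mean_j = float(np.mean([jaccard(fam_sets[i], fam_sets[j]) for i, j in pairs]))
    freq = {}
    for s in fam_sets:
        for f in s:
            freq[f] = freq.get(f, 0) + 1
    n = len(fam_sets)
    frequency = {f: c / n for f, c in sorted(freq.items(), key=lambda kv: -kv[1])}
    stable = sorted(f for f, c in freq.items() if c == n)
    return {
        "mean_pairwise_jaccard": mean_j,
        "selection_frequency": frequency,
        "mean_set_size": float(np.mean([len(s) for s in fam_sets])),
        "stable_families": stable,
    }
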