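"""Random-forest prediction of treatment-response slopes from baseline items.

Four nested feature sets are compared: model 0 (50 baseline clinical items),
model 1 (+21 baseline HAM-D single items), model 2 (+ early partial response
at week 2), model 3 (both expansions; 72 items).  Two regression targets are
supported: the patient's individual OLS slope of ln-transformed scores, and
the slope of the patient's assigned mixture component (cluster-derived
slope).  Forests use mtry = floor(sqrt(D)) candidate predictors per split;
explained variance is the adjusted R^2 of out-of-bag predictions; the
overall model p-value comes from a seeded target-permutation null, and
per-feature significance from Altmann-style permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .mixture import MixtureModel
from .prep import Cohort, RatingSeries
from .outcomes import individual_slope
from .synthetic import ClinicalTable, EARLY_RESPONSE_ITEM, HAMD_ITEMS, MODEL0_ITEMS

MODEL_FEATURES = {
    0: MODEL0_ITEMS,
    1: MODEL0_ITEMS + HAMD_ITEMS,
    2: MODEL0_ITEMS + [EARLY_RESPONSE_ITEM],
    3: MODEL0_ITEMS + HAMD_ITEMS + [EARLY_RESPONSE_ITEM],
}


@dataclass
class FeatureImportance:
    feature: str
    importance: float
    permutation_p: float


@dataclass
class PredictionResult:
    model_id: int
    target: str                     # "individual_slope" or "cluster_slope"
    r2: float
    r2_adj: float
    model_p: Optional[float]
    n: int
    d: int
    mtry: int
    importances: Optional[list] = None
    per_class_accuracy: Optional[dict] = None
    confusion: Optional[np.ndarray] = None


def impute_median(table: ClinicalTable) -> ClinicalTable:
    """Fill missing cells with the column median of the total sample.

    Dichotomous medians are rounded to {0, 1} with ties going to 0;
    categorical items take the column mode (ties to the lowest code).
    """
    df = table.data.copy()
    for col in df.columns:
        missing = df[col].isna()
        if not missing.any():
            continue
        observed = df.loc[~missing, col]
        if len(observed) == 0:
            raise ValueError(f"column {col!r} is fully missing")
        kind = table.item_types.get(col, "numerical")
        if kind == "categorical":
            fill = float(observed.mode().min())
        else:
            fill = float(observed.median())
            if kind == "dichotomous":
                fill = 0.0 if fill <= 0.5 else 1.0
        df.loc[missing, col] = fill
    return ClinicalTable(df, dict(table.item_types))


def early_partial_response(series: RatingSeries) -> bool:
    """>= 25% raw-score reduction from baseline by week 2 (inclusive)."""
    if series.lnvals is None:
        raise ValueError("series must be regularized")
    if series.last_week < 2:
        raise ValueError(f"patient {series.patient_id}: no week-2 value available")
    baseline = float(series.raw[0])
    week2 = float(series.raw[series.weeks == 2][0])
    return (baseline - week2) / baseline >= 0.25


def assemble_features(table: ClinicalTable, cohort: Optional[Cohort], model_id: int):
    """Feature matrix for one model variant (50 / 71 / 51 / 72 columns).

    The early-partial-response flag (models 2 and 3) is derived from the
    cohort's trajectories; patients discharged before week 2 count as
    responders (their score fell below the remission range by week 2).
    Categorical items remain integer-coded.
    """
    if model_id not in MODEL_FEATURES:
        raise ValueError(f"unknown model_id {model_id!r}; expected 0-3")
    cols = MODEL_FEATURES[model_id]
    df = table.data
    clinical_cols = [c for c in cols if c != EARLY_RESPONSE_ITEM]
    missing_cols = [c for c in clinical_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"clinical table lacks items: {missing_cols}")
    out = df[clinical_cols].copy()
    if EARLY_RESPONSE_ITEM in cols:
        if cohort is None:
            raise ValueError("model 2/3 features need the cohort for the week-2 response flag")
        flags = {}
        for s in cohort.series:
            if s.last_week >= 2:
                flags[s.patient_id] = float(early_partial_response(s))
            else:
                flags[s.patient_id] = 1.0
        out[EARLY_RESPONSE_ITEM] = [flags[pid] for pid in out.index]
    if out.isna().any().any():
        raise ValueError("feature matrix contains missing cells; impute first")
    return out


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> RandomForestRegressor:
    mtry = max(1, int(np.floor(np.sqrt(X.shape[1]))))
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=np.random.RandomState(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # few-tree fits may lack OOB coverage
        forest.fit(X, y)
    return forest


def _oob_r2(forest: RandomForestRegressor, y: np.ndarray) -> float:
    pred = forest.oob_prediction_
    covered = ~np.isnan(pred)
    res = float(((y[covered] - pred[covered]) ** 2).sum())
    tot = float(((y[covered] - y[covered].mean()) ** 2).sum())
    return 1.0 - res / tot


def rf_fit_evaluate(features, target, n_trees: int = 2000, seed: int = 0,
                    n_perm: int = 1000, model_id: int = 0,
                    target_name: str = "individual_slope") -> PredictionResult:
    """Random-forest regression with out-of-bag adjusted R^2.

    ``model_p`` is the rank p-value of the observed out-of-bag R^2 within a
    seeded target-permutation null (skipped when ``n_perm`` is 0).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    n, d = X.shape
    if np.std(y) == 0:
        raise ValueError("constant target")
    if n <= d + 1:
        raise ValueError("adjusted R^2 requires n > D + 1")
    forest = _fit_forest(X, y, n_trees, seed)
    r2 = _oob_r2(forest, y)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - d - 1)
    model_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for b in range(n_perm):
            yp = rng.permutation(y)
            fb = _fit_forest(X, yp, n_trees, seed + 1 + b)
            if _oob_r2(fb, yp) >= r2:
                exceed += 1
        model_p = (1 + exceed) / (1 + n_perm)
    mtry = max(1, int(np.floor(np.sqrt(d))))
    return PredictionResult(model_id=model_id, target=target_name, r2=r2,
                            r2_adj=r2_adj, model_p=model_p, n=n, d=d, mtry=mtry)


def _importances(forest: RandomForestRegressor, X, y, kind: str, seed: int,
                 n_repeats: int) -> np.ndarray:
    if kind == "impurity":
        return forest.feature_importances_
    if kind == "permutation":
        from sklearn.inspection import permutation_importance as ski

        res = ski(forest, X, y, n_repeats=n_repeats,
                  random_state=np.random.RandomState(seed), n_jobs=1)
        return res.importances_mean
    raise ValueError(f"unknown importance kind {kind!r}")


def permutation_importance(features, target, n_perm: int = 10000, seed: int = 0,
                           n_trees: int = 2000, importance_kind: str = "impurity",
                           n_repeats: int = 5, feature_names: Optional[Sequence[str]] = None):
    """Altmann permutation p-values for per-feature importances.

    The target is permuted ``n_perm`` times, the forest refit, and each
    feature's importance recollected under the null;
    p = (1 + #{null >= observed}) / (1 + n_perm), bounded below by
    1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if feature_names is None:
        feature_names = (list(features.columns) if hasattr(features, "columns")
                         else [f"x{j}" for j in range(X.shape[1])])
    forest = _fit_forest(X, y, n_trees, seed)
    observed = _importances(forest, X, y, importance_kind, seed, n_repeats)
    exceed = np.zeros(X.shape[1])
    rng = np.random.default_rng(seed)
    for b in range(n_perm):
        yp = rng.permutation(y)
        fb = _fit_forest(X, yp, n_trees, seed + 1 + b)
        null = _importances(fb, X, yp, importance_kind, seed + 1 + b, n_repeats)
        exceed += null >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return [FeatureImportance(name, float(obs), float(p))
            for name, obs, p in zip(feature_names, observed, pvals)]


def per_class_accuracy(true_labels, predicted_labels) -> Dict[int, float]:
    """One-vs-rest accuracy (TP + TN) / N for each class present."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if len(t) == 0:
        raise ValueError("empty inputs")
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    classes = np.unique(np.concatenate([t, p]))
    out = {}
    for c in classes:
        out[int(c)] = float(np.mean((t == c) == (p == c)))
    return out


def confusion_matrix(true_labels, predicted_labels, k: int) -> np.ndarray:
    t = np.asarray(true_labels, int)
    p = np.asarray(predicted_labels, int)
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (t, p), 1)
    return conf


def compare_r2(r2_a: float, r2_b: float, n_a: int, n_b: int):
    """Two-sided p for an R^2 difference via Fisher Z on r = sqrt(R^2)."""
    for r2 in (r2_a, r2_b):
        if not (0.0 <= r2 < 1.0):
            raise ValueError("R^2 values must lie in [0, 1)")
    if n_a <= 3 or n_b <= 3:
        raise ValueError("sample sizes must exceed 3")
    za = np.arctanh(np.sqrt(r2_a))
    zb = np.arctanh(np.sqrt(r2_b))
    z = (za - zb) / np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def map_slope_to_class(predicted_slope, model: MixtureModel) -> np.ndarray:
    """Nearest component slope in absolute difference; ties to lower index."""
    slopes = model.slopes
    pred = np.atleast_1d(np.asarray(predicted_slope, dtype=float))
    dist = np.abs(pred[:, None] - slopes[None, :])
    return np.argmin(dist, axis=1)


def predict_classes(features, target, model: MixtureModel, n_trees: int = 2000,
                    seed: int = 0) -> np.ndarray:
    """Out-of-bag slope predictions mapped to the nearest component class."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    forest = _fit_forest(X, y, n_trees, seed)
    pred = forest.oob_prediction_
    pred = np.where(np.isnan(pred), y.mean(), pred)
    return map_slope_to_class(pred, model)
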