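"""Malignancy classifier harness: gradient-boosted trees, random forest,
and a binomial GLM over CNV, microbial, or combined feature matrices.

Two training modes mirror the two stages of the study design:

* ``train_cv`` — five-fold stratified cross-validation over a small fixed
  hyperparameter grid, selecting by mean out-of-fold AUROC, then refitting
  the winner on all training data (baseline development).
* ``refit_fixed`` — a deterministic refit with frozen hyperparameters
  (gradient boosting: 100 rounds, depth 6, learning rate 0.3, gamma 0,
  all subsampling off; random forest: 500 trees, mtry = floor(sqrt(p));
  GLM: binomial maximum likelihood), used after pseudo-label extension
  where cross-validation is not repeated.

The positive class is "malignant" throughout; probabilities refer to it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .errors import InvalidInputError, InvalidParameterError, SchemaError
from .evaluate import roc_auc

__all__ = [
    "ModelSpec",
    "FittedModel",
    "resolve_mtry",
    "train_cv",
    "refit_fixed",
    "predict_proba",
    "combine_features",
    "METHODS",
]

METHODS = ("xgb", "rf", "glm")
_ALIASES = {
    "xgboost": "xgb",
    "gradient_boosted_trees": "xgb",
    "random_forest": "rf",
    "logistic_glm": "glm",
    "logistic": "glm",
}

FIXED_DEFAULTS: dict[str, dict] = {
    "xgb": dict(
        n_estimators=100,
        max_depth=6,
        learning_rate=0.3,
        gamma=0.0,
        colsample_bytree=1.0,
        min_child_weight=1,
        subsample=1.0,
    ),
    "rf": dict(n_estimators=500, max_features="mtry"),  # mtry -> floor(sqrt(p))
    "glm": {},
}

# Small fixed CV grids (reproducible stand-in for framework-default searches).
CV_GRIDS: dict[str, list[dict]] = {
    "xgb": [
        dict(n_estimators=100, max_depth=3, learning_rate=0.3),
        dict(n_estimators=100, max_depth=6, learning_rate=0.3),
    ],
    "rf": [dict(n_estimators=500, max_features="mtry")],
    "glm": [{}],
}


def resolve_mtry(p: int) -> int:
    """Random-forest mtry default: floor(sqrt(p)) features per split."""
    if p <= 0:
        raise InvalidInputError("need at least one feature")
    return int(math.floor(math.sqrt(p)))


@dataclass
class ModelSpec:
    """Which classifier to build and how."""

    method: str = "xgb"
    mode: str = "fixed"                      # {"cv_tuned", "fixed"}
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.method = _ALIASES.get(self.method, self.method)
        if self.method not in METHODS:
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if self.mode not in ("cv_tuned", "fixed"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")


@dataclass
class FittedModel:
    """A trained classifier plus the context needed to apply it safely."""

    spec: ModelSpec
    feature_ids: list[str]
    training_sample_ids: list[str]
    estimator: object
    cv_summary: pd.DataFrame | None = None   # per-fold AUROC of the winning setting


def _make_estimator(method: str, params: dict, seed: int, p: int):
    params = dict(params)
    if method == "xgb":
        merged = {**FIXED_DEFAULTS["xgb"], **params}
        return XGBClassifier(
            **merged,
            objective="binary:logistic",
            eval_metric="logloss",
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
        )
    if method == "rf":
        merged = {**FIXED_DEFAULTS["rf"], **params}
        if merged.get("max_features") == "mtry":
            merged["max_features"] = resolve_mtry(p)
        return RandomForestClassifier(**merged, n_jobs=1, random_state=seed)
    if method == "glm":
        # Binomial ML; near-zero L2 keeps the p >> n problem solvable.
        if p >= 200:
            warnings.warn(
                f"GLM with p={p} features is rank-deficient for typical n; "
                "fitting with a minimal L2 jitter"
            )
        return LogisticRegression(
            penalty="l2", C=1e8, solver="lbfgs", max_iter=500, random_state=seed
        )
    raise InvalidParameterError(f"unknown method {method!r}")


def _encode_labels(labels: pd.Series) -> np.ndarray:
    y = (labels.to_numpy() == "malignant").astype(int)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("labels contain a single class")
    return y


def _check_alignment(features: pd.DataFrame, labels: pd.Series) -> pd.Series:
    labels = labels.reindex(features.index)
    if labels.isna().any():
        missing = list(features.index[labels.isna()])
        raise InvalidInputError(f"samples without labels: {missing[:5]}")
    return labels


def train_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec,
    n_folds: int = 5,
) -> FittedModel:
    """Stratified k-fold CV over the method's grid; refit winner on all data.

    Hyperparameters are selected by mean out-of-fold AUROC; ties go to the
    first grid entry. Per-fold AUROCs of the winner are stored in
    ``cv_summary``.
    """
    if features.shape[1] == 0:
        raise InvalidInputError("feature matrix has no columns")
    labels = _check_alignment(features, labels)
    y = _encode_labels(labels)
    if min(np.bincount(y)) < n_folds:
        raise InvalidInputError(f"need >= {n_folds} samples per class for {n_folds}-fold CV")
    X = features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))

    grid = CV_GRIDS[spec.method]
    if spec.hyperparameters:
        grid = [{**g, **spec.hyperparameters} for g in grid]
    mean_aucs, fold_tables = [], []
    for params in grid:
        fold_aucs = []
        for train_idx, test_idx in folds:
            est = _make_estimator(spec.method, params, spec.seed, X.shape[1])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X[train_idx], y[train_idx])
                p_oof = est.predict_proba(X[test_idx])[:, 1]
            fold_aucs.append(roc_auc(y[test_idx], p_oof))
        mean_aucs.append(float(np.mean(fold_aucs)))
        fold_tables.append(fold_aucs)
    best = int(np.argmax(mean_aucs))
    winner = grid[best]

    est = _make_estimator(spec.method, winner, spec.seed, X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    cv_summary = pd.DataFrame(
        {
            "fold": np.arange(n_folds),
            "auroc": fold_tables[best],
        }
    )
    cv_summary.attrs["winning_hyperparameters"] = winner
    cv_summary.attrs["grid_mean_auroc"] = mean_aucs
    out_spec = ModelSpec(
        method=spec.method, mode="cv_tuned", hyperparameters=dict(winner), seed=spec.seed
    )
    return FittedModel(
        spec=out_spec,
        feature_ids=list(features.columns),
        training_sample_ids=list(features.index),
        estimator=est,
        cv_summary=cv_summary,
    )


def refit_fixed(features: pd.DataFrame, labels: pd.Series, spec: ModelSpec) -> FittedModel:
    """Deterministic refit with frozen hyperparameters (no cross-validation)."""
    if features.shape[1] == 0:
        raise InvalidInputError("feature matrix has no columns")
    labels = _check_alignment(features, labels)
    y = _encode_labels(labels)
    X = features.to_numpy(dtype=float)
    params = {**FIXED_DEFAULTS[spec.method], **spec.hyperparameters}
    est = _make_estimator(spec.method, params, spec.seed, X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    out_spec = ModelSpec(
        method=spec.method, mode="fixed", hyperparameters=dict(params), seed=spec.seed
    )
    return FittedModel(
        spec=out_spec,
        feature_ids=list(features.columns),
        training_sample_ids=list(features.index),
        estimator=est,
    )


def predict_proba(model: FittedModel, features: pd.DataFrame) -> pd.Series:
    """Per-sample probability of malignancy, columns checked against the model."""
    missing = [c for c in model.feature_ids if c not in features.columns]
    if missing:
        raise SchemaError(f"missing feature columns: {missing[:5]}")
    X = features[model.feature_ids].to_numpy(dtype=float)
    p = model.estimator.predict_proba(X)[:, 1]
    return pd.Series(np.clip(p, 0.0, 1.0), index=features.index, name="p_malignant")


def combine_features(cnv: pd.DataFrame, micro: pd.DataFrame) -> pd.DataFrame:
    """Column-concatenate CNV and microbial features with namespaced ids.

    Both inputs are samples x features over the same sample set; columns
    come out as ``cnv:<id>`` then ``micro:<id>``, values unscaled (the tree
    models are scale-free and the GLM is documented as unscaled).
    """
    if set(cnv.index) != set(micro.index):
        only_cnv = sorted(set(cnv.index) - set(micro.index))
        only_micro = sorted(set(micro.index) - set(cnv.index))
        raise InvalidInputError(
            f"sample mismatch; cnv-only={only_cnv[:5]}, micro-only={only_micro[:5]}"
        )
    micro = micro.reindex(cnv.index)
    left = cnv.rename(columns={c: f"cnv:{c}" for c in cnv.columns})
    right = micro.rename(columns={c: f"micro:{c}" for c in micro.columns})
    return pd.concat([left, right], axis=1)
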