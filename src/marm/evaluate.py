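"""Performance metrics, bootstrap confidence intervals, model comparison,
and mapping of top model features back to genomic regions.

Conventions: the positive class is "malignant"; the default decision
threshold on predicted probability is 0.5; AUC uses the tie-aware
Mann-Whitney formulation (ties get half credit); confidence intervals are
class-stratified bootstrap percentile intervals with a fixed seed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import InvalidParameterError, LeakageError, UndefinedMetricError

__all__ = [
    "EvaluationResult",
    "confusion_metrics",
    "roc_auc",
    "metric_ci",
    "evaluate_predictions",
    "compare_experiments",
    "rank_feature_regions",
]

POSITIVE = "malignant"


@dataclass
class EvaluationResult:
    """Point metrics with 95% CIs for one model on one evaluation set."""

    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    auc: float
    ci_sensitivity: tuple[float, float]
    ci_specificity: tuple[float, float]
    ci_accuracy: tuple[float, float]
    n_pos: int
    n_neg: int
    threshold: float


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "bif":
        return arr.astype(int)
    return (arr == POSITIVE).astype(int)


def confusion_metrics(truth, predicted) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and Youden index at a fixed call.

    youden = sensitivity + specificity - 1, computed exactly from the same
    unrounded rates.
    """
    y = _as_binary(truth)
    yhat = _as_binary(predicted)
    if y.shape != yhat.shape:
        raise InvalidParameterError("truth/prediction length mismatch")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both classes must be present in truth")
    tp = int(((y == 1) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    acc = (tp + tn) / len(y)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "youden": sens + spec - 1.0,
    }


def roc_auc(truth, scores) -> float:
    """Tie-aware AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Constant scores return 0.5 with a warning instead of failing.
    """
    y = _as_binary(truth)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedMetricError("both classes must be present for AUC")
    if np.all(s == s[0]):
        warnings.warn("constant scores; AUC undefined, returning 0.5")
        return 0.5
    return float(roc_auc_score(y, s))


_METRIC_FNS = {
    "sensitivity": lambda y, yhat: confusion_metrics(y, yhat)["sensitivity"],
    "specificity": lambda y, yhat: confusion_metrics(y, yhat)["specificity"],
    "accuracy": lambda y, yhat: confusion_metrics(y, yhat)["accuracy"],
    "youden": lambda y, yhat: confusion_metrics(y, yhat)["youden"],
}


def metric_ci(
    truth,
    predicted,
    metric: str = "accuracy",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Class-stratified bootstrap percentile CI for a confusion metric.

    Resampling is within each truth class, so every resample keeps both
    classes and the metric stays defined. Deterministic given the seed.
    """
    if metric not in _METRIC_FNS:
        raise InvalidParameterError(f"unknown metric {metric!r}")
    y = _as_binary(truth)
    yhat = _as_binary(predicted)
    if len(y) < 10:
        raise InvalidParameterError("need n >= 10 for a bootstrap CI")
    fn = _METRIC_FNS[metric]
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise UndefinedMetricError("both classes must be present in truth")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        stats[b] = fn(y[idx], yhat[idx])
    alpha = (1 - level) / 2
    lo, hi = np.quantile(stats, [alpha, 1 - alpha])
    return float(lo), float(hi)


def evaluate_predictions(
    truth,
    probabilities,
    threshold: float = 0.5,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationResult:
    """All reported metrics for one probability vector at one threshold."""
    y = _as_binary(truth)
    p = np.asarray(probabilities, dtype=float)
    yhat = (p > threshold).astype(int)
    m = confusion_metrics(y, yhat)
    auc = roc_auc(y, p)
    cis = {
        name: metric_ci(y, yhat, metric=name, level=level, n_boot=n_boot, seed=seed)
        for name in ("sensitivity", "specificity", "accuracy")
    }
    return EvaluationResult(
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        accuracy=m["accuracy"],
        youden=m["youden"],
        auc=auc,
        ci_sensitivity=cis["sensitivity"],
        ci_specificity=cis["specificity"],
        ci_accuracy=cis["accuracy"],
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
        threshold=threshold,
    )


def compare_experiments(
    models: list[dict],
    eval_features_by_type: dict[str, pd.DataFrame],
    eval_labels: pd.Series,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Unified long-format comparison table over (method, feature, strategy).

    Each entry of ``models`` is a dict with keys ``method``, ``feature``,
    ``strategy`` and ``model`` (a FittedModel). Every model is scored on
    the evaluation features matching its feature type. Any overlap between
    a model's training samples and the evaluation set is a fatal leakage
    error naming the offending ids.
    """
    from .classify import predict_proba  # local import avoids a cycle

    eval_ids = set(eval_labels.index)
    rows = []
    for entry in models:
        model = entry["model"]
        overlap = sorted(eval_ids & set(model.training_sample_ids))
        if overlap:
            raise LeakageError(
                f"{entry['method']}/{entry['feature']}/{entry['strategy']}: evaluation "
                f"samples found in training set: {overlap[:10]}"
            )
        feats = eval_features_by_type[entry["feature"]]
        probs = predict_proba(model, feats.loc[eval_labels.index])
        res = evaluate_predictions(
            eval_labels, probs, threshold=threshold, n_boot=n_boot, seed=seed
        )
        rows.append(
            {
                "method": entry["method"],
                "feature": entry["feature"],
                "strategy": entry["strategy"],
                "sensitivity": res.sensitivity,
                "sensitivity_lo": res.ci_sensitivity[0],
                "sensitivity_hi": res.ci_sensitivity[1],
                "specificity": res.specificity,
                "specificity_lo": res.ci_specificity[0],
                "specificity_hi": res.ci_specificity[1],
                "accuracy": res.accuracy,
                "accuracy_lo": res.ci_accuracy[0],
                "accuracy_hi": res.ci_accuracy[1],
                "youden": res.youden,
                "auc": res.auc,
                "n_pos": res.n_pos,
                "n_neg": res.n_neg,
                "threshold": res.threshold,
            }
        )
    return pd.DataFrame(rows)


_BIN_ID_RE = re.compile(r"^(?:cnv:)?(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _importances(model) -> np.ndarray:
    est = model.estimator
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    if hasattr(est, "coef_"):
        return np.abs(np.asarray(est.coef_, dtype=float).ravel())
    raise InvalidParameterError("model exposes no feature importances")


def rank_feature_regions(model, bins=None, top_k: int = 10) -> pd.DataFrame:
    """Top features by native importance, CNV features mapped to intervals.

    Importance is the method's own measure (gain for boosted trees,
    impurity decrease for forests, |coefficient| for the GLM). Feature ids
    of the form ``[cnv:]chrom:start-end`` resolve to genomic coordinates;
    other (e.g. microbial) features report NaN coordinates. All-zero
    importances yield an empty table with a warning — no arbitrary order
    is presented as meaningful.
    """
    if top_k < 0:
        raise InvalidParameterError("top_k must be >= 0")
    imp = _importances(model)
    p = len(model.feature_ids)
    if top_k > p:
        warnings.warn(f"top_k={top_k} exceeds feature count {p}; truncating")
        top_k = p
    if top_k == 0:
        return pd.DataFrame(columns=["feature_id", "chrom", "start", "end", "importance"])
    if np.all(imp == 0):
        warnings.warn("all feature importances are zero; returning empty ranking")
        return pd.DataFrame(columns=["feature_id", "chrom", "start", "end", "importance"])
    order = np.argsort(-imp, kind="stable")[:top_k]
    rows = []
    for i in order:
        fid = model.feature_ids[i]
        m = _BIN_ID_RE.match(fid)
        if m:
            rows.append(
                {
                    "feature_id": fid,
                    "chrom": m["chrom"],
                    "start": int(m["start"]),
                    "end": int(m["end"]),
                    "importance": imp[i],
                }
            )
        else:
            rows.append(
                {
                    "feature_id": fid,
                    "chrom": None,
                    "start": np.nan,
                    "end": np.nan,
                    "importance": imp[i],
                }
            )
    return pd.DataFrame(rows)
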