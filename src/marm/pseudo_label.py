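"""Pseudo-label extension training with weakly labeled samples.

A baseline model trained on high-quality labels scores every weakly
labeled sample; only samples predicted malignant with probability
*strictly* greater than the confidence threshold (default 0.8) are
promoted to pseudo-positives, appended to the high-quality training set as
"malignant", and the model is refit once with fixed hyperparameters.
Predicted non-malignant weak samples are discarded, never added as
negatives, and high-quality labels are never modified. This is a single
self-training pass, not an iterative scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FittedModel, ModelSpec, predict_proba, refit_fixed
from .errors import InvalidInputError, InvalidParameterError
from .evaluate import evaluate_predictions

__all__ = [
    "PseudoLabelSelection",
    "select_pseudo_positives",
    "extend_and_retrain",
    "threshold_sensitivity",
]

DEFAULT_THRESHOLD = 0.8


@dataclass
class PseudoLabelSelection:
    """Which weak samples were promoted, at what threshold, and why."""

    threshold: float
    selected_ids: list[str]
    probabilities: pd.Series          # over the full weak set
    assigned_label: str = field(default="malignant", init=False)


def select_pseudo_positives(
    probs: pd.Series, threshold: float = DEFAULT_THRESHOLD
) -> PseudoLabelSelection:
    """Select weak samples with predicted malignancy probability > threshold.

    The boundary is excluded (strictly greater); selection is
    deterministic and only ever assigns the positive label.
    """
    if not 0 <= threshold < 1:
        raise InvalidParameterError(f"threshold={threshold} outside [0, 1)")
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidParameterError("probabilities must lie in [0, 1]")
    selected = [sid for sid, pi in probs.items() if pi > threshold]
    return PseudoLabelSelection(
        threshold=threshold, selected_ids=selected, probabilities=probs.copy()
    )


def extend_and_retrain(
    setA_features: pd.DataFrame,
    setA_labels: pd.Series,
    weak_features: pd.DataFrame,
    selection: PseudoLabelSelection,
    spec: ModelSpec,
) -> tuple[FittedModel, dict]:
    """Refit on Set A plus the selected pseudo-positives, fixed parameters.

    Returns the extended model and an audit record (threshold, counts,
    selected ids, probability summary). Set A labels pass through
    untouched; an overlap between Set A and the weak set is an error.
    """
    overlap = sorted(set(setA_features.index) & set(weak_features.index))
    if overlap:
        raise InvalidInputError(f"samples in both Set A and weak set: {overlap[:10]}")
    unknown = sorted(set(selection.selected_ids) - set(weak_features.index))
    if unknown:
        raise InvalidInputError(f"selected ids not in weak set: {unknown[:10]}")

    extra = weak_features.loc[selection.selected_ids]
    features = pd.concat([setA_features, extra], axis=0)
    labels = pd.concat(
        [
            setA_labels.reindex(setA_features.index),
            pd.Series(selection.assigned_label, index=extra.index),
        ]
    )
    model = refit_fixed(features, labels, spec)
    probs = selection.probabilities
    audit = {
        "threshold": selection.threshold,
        "n_weak": int(len(weak_features)),
        "n_selected": int(len(selection.selected_ids)),
        "selected_ids": list(selection.selected_ids),
        "probability_summary": {
            "min": float(probs.min()) if len(probs) else None,
            "median": float(probs.median()) if len(probs) else None,
            "max": float(probs.max()) if len(probs) else None,
        },
    }
    return model, audit


def threshold_sensitivity(
    baseline_model: FittedModel,
    setA_features: pd.DataFrame,
    setA_labels: pd.Series,
    weak_features: pd.DataFrame,
    eval_features: pd.DataFrame,
    eval_labels: pd.Series,
    spec: ModelSpec,
    thresholds: tuple[float, ...] = (0.7, 0.8, 0.9),
    decision_threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """One metrics row per confidence threshold on a fixed evaluation set.

    For each threshold: score the weak set with the baseline model, select
    pseudo-positives, extend and retrain, evaluate. The evaluation set must
    be disjoint from Set A and the weak pool (checked upstream by the
    comparison harness; enforced here for training overlap).
    """
    eval_ids = set(eval_labels.index)
    leak = sorted(eval_ids & (set(setA_features.index) | set(weak_features.index)))
    if leak:
        raise InvalidInputError(f"evaluation samples overlap training pools: {leak[:10]}")
    weak_probs = predict_proba(baseline_model, weak_features)
    rows = []
    for t in thresholds:
        selection = select_pseudo_positives(weak_probs, threshold=t)
        model, audit = extend_and_retrain(
            setA_features, setA_labels, weak_features, selection, spec
        )
        probs = predict_proba(model, eval_features.loc[eval_labels.index])
        res = evaluate_predictions(
            eval_labels, probs, threshold=decision_threshold, n_boot=n_boot, seed=seed
        )
        rows.append(
            {
                "threshold": t,
                "n_selected": audit["n_selected"],
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "accuracy": res.accuracy,
                "youden": res.youden,
                "auc": res.auc,
            }
        )
    return pd.DataFrame(rows)
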