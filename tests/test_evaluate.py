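"""Metrics against hand-computed contingency tables, tie-aware AUC against
an exhaustive pair oracle, bootstrap CI behavior, comparison-table
contracts and feature-region ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from marm.classify import ModelSpec, refit_fixed
from marm.errors import LeakageError, UndefinedMetricError
from marm.evaluate import (
    compare_experiments,
    confusion_metrics,
    evaluate_predictions,
    metric_ci,
    rank_feature_regions,
    roc_auc,
)


def test_confusion_metrics_hand_computed():
    # TP=3, FN=1, TN=4, FP=2
    truth = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    pred = [1, 1, 1, 0, 0, 0, 0, 0, 1, 1]
    m = confusion_metrics(truth, pred)
    assert m["sensitivity"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(2 / 3)
    assert m["accuracy"] == pytest.approx(0.7)
    assert m["youden"] == pytest.approx(0.75 + 2 / 3 - 1)


def test_confusion_metrics_degenerate_predictors():
    truth = [1, 1, 0, 0]
    perfect = confusion_metrics(truth, truth)
    assert [perfect[k] for k in ("sensitivity", "specificity", "accuracy", "youden")] == [
        1, 1, 1, 1,
    ]
    always = confusion_metrics(truth, [1, 1, 1, 1])
    assert always["sensitivity"] == 1 and always["specificity"] == 0
    assert always["accuracy"] == 0.5 and always["youden"] == 0
    with pytest.raises(UndefinedMetricError):
        confusion_metrics([1, 1], [1, 0])


def _auc_pair_oracle(y, s):
    y, s = np.asarray(y), np.asarray(s, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_examples_and_tie_handling():
    assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
    y = [1, 1, 1, 0, 0, 0]
    s = [0.9, 0.5, 0.5, 0.5, 0.2, 0.1]
    assert roc_auc(y, s) == pytest.approx(_auc_pair_oracle(y, s), abs=1e-12)
    inv = [0 if v else 1 for v in y]
    assert roc_auc(inv, s) == pytest.approx(1 - roc_auc(y, s), abs=1e-12)
    with pytest.warns(UserWarning):
        assert roc_auc([1, 0], [0.5, 0.5]) == 0.5


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(st.booleans(), min_size=4, max_size=30),
    st.data(),
)
def test_auc_matches_pair_oracle(labels, data):
    y = np.array(labels, dtype=int)
    if y.sum() in (0, len(y)):
        y[0] = 1 - y[0]
    if y.sum() in (0, len(y)):
        return
    s = data.draw(
        st.lists(
            st.integers(min_value=0, max_value=5),
            min_size=len(y), max_size=len(y),
        )
    )
    assert roc_auc(y, s) == pytest.approx(_auc_pair_oracle(y, s), abs=1e-10)


def test_metric_ci_degenerate_and_deterministic():
    truth = [1] * 10 + [0] * 10
    assert metric_ci(truth, truth, "accuracy") == (1.0, 1.0)
    pred = [1] * 8 + [0, 0] + [0] * 9 + [1]
    a = metric_ci(truth, pred, "sensitivity", seed=9)
    b = metric_ci(truth, pred, "sensitivity", seed=9)
    assert a == b


def test_metric_ci_matches_binomial_enumeration():
    """Half-correct predictions on 50+50: the stratified bootstrap accuracy
    is Binomial(100, 0.5)/100, so the percentile CI must sit within 0.02 of
    the exact binomial percentile bounds."""
    truth = [1] * 50 + [0] * 50
    pred = [1] * 25 + [0] * 25 + [0] * 25 + [1] * 25
    lo, hi = metric_ci(truth, pred, "accuracy", n_boot=4000, seed=1)
    exact_lo = stats.binom.ppf(0.025, 100, 0.5) / 100
    exact_hi = stats.binom.ppf(0.975, 100, 0.5) / 100
    assert lo == pytest.approx(exact_lo, abs=0.02)
    assert hi == pytest.approx(exact_hi, abs=0.02)


def test_ci_contains_point_and_narrows_with_n(rng):
    for n, max_width in ((40, 1.0), (400, 0.2)):
        truth = np.array([1, 0] * (n // 2))
        pred = truth.copy()
        flip = rng.choice(n, size=n // 5, replace=False)
        pred[flip] = 1 - pred[flip]
        point = confusion_metrics(truth, pred)["accuracy"]
        lo, hi = metric_ci(truth, pred, "accuracy", n_boot=500, seed=2)
        assert lo <= point <= hi
        assert hi - lo < max_width


def test_evaluate_predictions_youden_identity(rng):
    truth = np.array([1] * 30 + [0] * 30)
    probs = np.clip(rng.normal(truth * 0.6 + 0.2, 0.2), 0, 1)
    res = evaluate_predictions(truth, probs, n_boot=100)
    assert res.youden == pytest.approx(res.sensitivity + res.specificity - 1, abs=1e-15)
    assert res.n_pos == 30 and res.n_neg == 30


@pytest.fixture
def toy_models(rng):
    idx = [f"t{i}" for i in range(40)]
    X = pd.DataFrame(rng.normal(size=(40, 5)), index=idx,
                     columns=[f"f{j}" for j in range(5)])
    y = pd.Series(["malignant", "non_malignant"] * 20, index=idx)
    X.loc[y == "malignant", "f0"] += 2.0
    model = refit_fixed(X, y, ModelSpec(method="glm", seed=0))
    eidx = [f"e{i}" for i in range(20)]
    Xe = pd.DataFrame(rng.normal(size=(20, 5)), index=eidx, columns=X.columns)
    ye = pd.Series(["malignant", "non_malignant"] * 10, index=eidx)
    Xe.loc[ye == "malignant", "f0"] += 2.0
    return model, X, y, Xe, ye


def test_compare_experiments_rows_and_purity(toy_models):
    model, X, y, Xe, ye = toy_models
    entries = [
        {"method": "GLM", "feature": "CNV", "strategy": "Set A", "model": model},
        {"method": "GLM", "feature": "CNV", "strategy": "Set A", "model": model},
    ]
    table = compare_experiments(entries, {"CNV": Xe}, ye, n_boot=100)
    assert len(table) == 2
    pd.testing.assert_series_equal(
        table.iloc[0].drop(["method", "feature", "strategy"]),
        table.iloc[1].drop(["method", "feature", "strategy"]),
        check_names=False,
    )


def test_compare_experiments_detects_leakage(toy_models):
    model, X, y, Xe, ye = toy_models
    leaky_labels = pd.concat([ye, y.iloc[:2]])
    leaky_feats = pd.concat([Xe, X.iloc[:2]])
    with pytest.raises(LeakageError, match="t0"):
        compare_experiments(
            [{"method": "GLM", "feature": "CNV", "strategy": "Set A", "model": model}],
            {"CNV": leaky_feats},
            leaky_labels,
        )


def test_rank_feature_regions_parsing_and_edges(rng):
    idx = [f"s{i}" for i in range(30)]
    cols = ["chr1:0-1000000", "chr1:1000000-2000000", "micro:Escherichia coli"]
    X = pd.DataFrame(rng.normal(size=(30, 3)), index=idx, columns=cols)
    y = pd.Series(["malignant", "non_malignant"] * 15, index=idx)
    X.loc[y == "malignant", cols[0]] += 3.0
    model = refit_fixed(X, y, ModelSpec(method="rf", seed=0))
    table = rank_feature_regions(model, top_k=3)
    assert table.iloc[0]["feature_id"] == cols[0]
    assert table.iloc[0]["chrom"] == "chr1"
    assert table.iloc[0][["start", "end"]].tolist() == [0, 1000000]
    micro_rows = table[table["feature_id"] == cols[2]]
    assert micro_rows["chrom"].isna().all()
    assert len(rank_feature_regions(model, top_k=0)) == 0
    with pytest.warns(UserWarning, match="truncating"):
        t = rank_feature_regions(model, top_k=10)
    assert len(t) == 3


def test_rank_feature_regions_refuses_arbitrary_order(rng):
    idx = [f"s{i}" for i in range(20)]
    X = pd.DataFrame(np.ones((20, 4)), index=idx, columns=[f"f{j}" for j in range(4)])
    y = pd.Series(["malignant", "non_malignant"] * 10, index=idx)
    model = refit_fixed(X, y, ModelSpec(method="rf", seed=0))
    with pytest.warns(UserWarning, match="zero"):
        table = rank_feature_regions(model, top_k=4)
    assert len(table) == 0
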