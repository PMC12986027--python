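import numpy as np
import pandas as pd
import pytest

from cappm.log import label_cases
from cappm.modeling import (
    auprc,
    auroc,
    brier,
    calibration,
    confusion,
    early_warning_window,
    evaluate,
    importance,
    train,
    tree_contributions,
)
from cappm.prefixes import generate_prefixes
from conftest import make_log
from oracles import pairwise_auroc

rng = np.random.default_rng(12345)


def _toy(n=200, informative=True, seed=0):
    r = np.random.default_rng(seed)
    X = pd.DataFrame(r.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)])
    if informative:
        y = (X["f0"] + 0.3 * r.normal(size=n) > 0).astype(int)
    else:
        y = r.integers(0, 2, size=n)
    return X, y.values if hasattr(y, "values") else y


@pytest.mark.parametrize(
    "algorithm", ["decision_tree", "random_forest", "gradient_boosting", "extra_trees", "adaboost"]
)
def test_train_separable_and_deterministic(algorithm):
    X, y = _toy(seed=1)
    m1 = train(X, y, algorithm, seed=7)
    m2 = train(X, y, algorithm, seed=7)
    assert np.allclose(m1.predict_proba(X), m2.predict_proba(X))
    assert auroc(y, m1.predict_proba(X)) > 0.95  # near-separable training data


def test_train_rejects_single_class():
    X, _ = _toy()
    with pytest.raises(ValueError, match="single class"):
        train(X, np.zeros(len(X), dtype=int), "random_forest")


def test_no_signal_null_auroc_near_half():
    aucs = []
    for s in range(10):
        X, y = _toy(n=400, informative=False, seed=s)
        half = 300
        m = train(X.iloc[:half], y[:half], "gradient_boosting", seed=s)
        aucs.append(auroc(y[half:], m.predict_proba(X.iloc[half:])))
    assert abs(np.mean(aucs) - 0.5) < 0.07


def test_auroc_matches_pairwise_concordance():
    y = [0, 1, 0, 1]
    p = [0.1, 0.9, 0.8, 0.7]
    assert auroc(y, p) == pytest.approx(0.75)
    assert auroc(y, p) == pytest.approx(pairwise_auroc(y, p))
    for s in range(5):
        r = np.random.default_rng(s)
        yy = r.integers(0, 2, size=30)
        if yy.min() == yy.max():
            continue
        pp = np.round(r.random(30), 1)  # coarse grid to exercise ties
        assert auroc(yy, pp) == pytest.approx(pairwise_auroc(yy, pp))


def test_auroc_auprc_edges():
    y = [0, 0, 1, 1]
    assert auroc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auprc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
    # constant scores: no discrimination; PR no-skill equals prevalence
    assert auroc(y, [0.5] * 4) == 0.5
    assert auprc(y, [0.5] * 4) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        auroc([1, 1], [0.2, 0.3])


def test_brier_values():
    assert brier([1, 0], [1.0, 0.0]) == 0.0
    assert brier([1, 0, 1, 0], [0.5] * 4) == 0.25
    assert brier([1, 0], [0.8, 0.3]) == pytest.approx(0.065)
    # predictions at the base rate never exceed 0.25
    y = (np.arange(100) < 30).astype(float)
    assert brier(y, np.full(100, y.mean())) <= 0.25 + 1e-9


def test_calibration_bins():
    r = np.random.default_rng(0)
    p = r.random(10_000)
    y = (r.random(10_000) < p).astype(int)
    bins = calibration(y, p, n_bins=10)
    occupied = bins[~bins["empty"]]
    assert len(occupied) == 10
    assert (occupied["mean_predicted"] - occupied["event_rate"]).abs().max() < 0.05
    # all p in one bin -> single occupied bin, flagged empties retained
    bins2 = calibration([0, 1], [0.42, 0.44], n_bins=10)
    assert (~bins2["empty"]).sum() == 1 and len(bins2) == 10
    bins3 = calibration([0, 0, 0], [0.1, 0.6, 0.9], n_bins=5)
    assert (bins3.loc[~bins3["empty"], "event_rate"] == 0).all()


def test_confusion_counts_and_rates():
    # printed-cell reconstruction: 19/88 deteriorations detected, 700/715 controls kept
    y = np.array([1] * 88 + [0] * 715)
    p = np.array([0.9] * 19 + [0.1] * 69 + [0.9] * 15 + [0.1] * 700)
    cm = confusion(y, p, 0.5)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (19, 69, 15, 700)
    assert cm.sensitivity == pytest.approx(19 / 88)
    assert round(cm.sensitivity, 2) == 0.22
    assert cm.specificity == pytest.approx(700 / 715)
    assert round(cm.specificity, 2) == 0.98
    assert cm.total == len(y)
    # threshold 0 marks everything positive
    cm0 = confusion(y, p, 0.0)
    assert cm0.sensitivity == 1.0 and cm0.specificity == 0.0


@pytest.mark.parametrize("algorithm", ["decision_tree", "random_forest", "gradient_boosting"])
def test_contributions_additivity(algorithm):
    X, y = _toy(n=150, seed=2)
    m = train(X, y, algorithm, seed=0)
    contribs, base = tree_contributions(m, X)
    total = base + contribs.sum(axis=1)
    if algorithm == "gradient_boosting":
        expected = m.estimator.decision_function(X.values)
    else:
        expected = m.estimator.predict_proba(X.values)[:, 1]
    assert np.allclose(total, expected, atol=1e-8)


def test_contributions_unsupported_model():
    X, y = _toy(n=60, seed=3)
    m = train(X, y, "adaboost", seed=0)
    with pytest.raises(TypeError, match="unsupported"):
        tree_contributions(m, X)


def test_importance_recovers_informative_feature():
    hits = 0
    for s in range(10):
        r = np.random.default_rng(s)
        X = pd.DataFrame(r.normal(size=(400, 10)), columns=[f"f{i}" for i in range(10)])
        y = (X["f0"] > 0).astype(int).values
        m = train(X, y, "gradient_boosting", seed=s)
        imp = importance(m, X)
        hits += imp.iloc[0]["feature"] == "f0"
        # zero-variance feature gets zero contribution
        X2 = X.copy()
        X2["f9"] = 1.0
        m2 = train(X2, y, "gradient_boosting", seed=s)
        imp2 = importance(m2, X2).set_index("feature")
        assert imp2.loc["f9", "mean_abs_contribution"] == 0.0
    assert hits >= 9


def test_early_warning_window():
    log = make_log(
        [
            ("c1", ["A", "B", "C", "D", "Admission IC"]),  # det 4 h after start
            ("c2", ["A", "B", "Release A"]),
            ("c3", ["A", "Admission IC", "B", "C"]),  # deteriorates before any prefix
        ]
    )
    labels = label_cases(log)
    prefixes = generate_prefixes(log, labels, [3])
    ew = early_warning_window(prefixes, labels)
    # c1: longest prefix ends at hour 2, deterioration at hour 4 -> 2 h
    assert ew.windows_hours == {"c1": pytest.approx(2.0)}
    assert ew.median == pytest.approx(2.0)
    assert ew.q1 == ew.q3 == pytest.approx(2.0)  # all windows equal
    assert ew.n_excluded == 1
    assert all(w > 0 for w in ew.windows_hours.values())


def test_early_warning_median_order_statistic():
    import numpy as np

    vals = np.array([1, 2, 3, 4, 100])
    assert float(np.percentile(vals, 50)) == 3.0  # robustness to the outlier


def test_evaluate_report_consistency():
    X, y = _toy(n=300, seed=4)
    m = train(X.iloc[:200], y[:200], "gradient_boosting", seed=0)
    rep = evaluate(m, X.iloc[200:], y[200:], threshold=0.5)
    assert 0 <= rep.auroc <= 1 and 0 <= rep.brier <= 1
    assert rep.confusion.total == rep.n_test == 100
    assert rep.prevalence == pytest.approx(np.mean(y[200:]))
    d = rep.to_dict()
    assert d["confusion"]["tp"] + d["confusion"]["fn"] == int(np.sum(y[200:]))
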