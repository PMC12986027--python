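"""Classifier training, discrimination/calibration metrics and interpretability.

Five tree-based classifiers are supported (decision tree, random forest,
gradient boosting, extra trees, AdaBoost), trained on prefix-level feature
matrices and evaluated at prefix level with AUROC, AUPRC, Brier score,
reliability bins and a thresholded confusion matrix. Feature attributions are
additive tree-path contributions: walking each sample's decision path, the
change in node value at a split is credited to the split feature, so per-row
contributions sum to the prediction minus the ensemble base value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.tree import DecisionTreeClassifier

from .prefixes import Prefix

ALGORITHMS = {
    "decision_tree": DecisionTreeClassifier,
    "random_forest": RandomForestClassifier,
    "gradient_boosting": GradientBoostingClassifier,
    "extra_trees": ExtraTreesClassifier,
    "adaboost": AdaBoostClassifier,
}


@dataclass
class TrainedModel:
    """A fitted classifier plus the bookkeeping needed to apply it honestly."""

    algorithm: str
    estimator: object
    feature_names: list
    feature_set: str
    medians: dict = field(default_factory=dict)
    seed: int = 0

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of deterioration, applying stored training medians to gaps."""
        X = X[self.feature_names]
        if self.medians:
            X = X.fillna(self.medians)
        return self.estimator.predict_proba(X.values)[:, 1]


def train(
    X: pd.DataFrame,
    y: Sequence[int],
    algorithm: str = "gradient_boosting",
    seed: int = 0,
    feature_set: str = "cappm",
    medians: Mapping[str, float] | None = None,
) -> TrainedModel:
    """Fit one of the supported classifiers with library defaults and a fixed seed."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = ALGORITHMS[algorithm](random_state=seed)
    est.fit(X.values, y)
    return TrainedModel(
        algorithm, est, list(X.columns), feature_set, dict(medians or {}), seed
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auroc(y: Sequence[int], p: Sequence[float]) -> float:
    """Area under the ROC curve (tie-corrected rank statistic)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC undefined: y contains a single class")
    return float(roc_auc_score(y, p))


def auprc(y: Sequence[int], p: Sequence[float]) -> float:
    """Area under the precision-recall curve (interpolation-free average precision)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("AUPRC undefined: y contains a single class")
    return float(average_precision_score(y, p))


def brier(y: Sequence[int], p: Sequence[float]) -> float:
    """Mean squared difference between predicted probabilities and outcomes."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def calibration(y: Sequence[int], p: Sequence[float], n_bins: int = 10) -> pd.DataFrame:
    """Equal-width reliability bins on [0, 1].

    Per bin: mean predicted probability, observed event frequency and count.
    Empty bins are kept and flagged (``empty`` column), never dropped silently.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        count = int(mask.sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_predicted": float(p[mask].mean()) if count else np.nan,
                "event_rate": float(y[mask].mean()) if count else np.nan,
                "count": count,
                "empty": count == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y: Sequence[int], p: Sequence[float], threshold: float = 0.5) -> ConfusionMatrix:
    """Counts at a probability threshold; p >= threshold predicts deterioration."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    y = np.asarray(y)
    pred = np.asarray(p) >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Additive tree-path feature contributions
# ---------------------------------------------------------------------------

def _tree_node_values_classifier(tree) -> np.ndarray:
    v = tree.value.reshape(tree.node_count, -1)
    return v[:, 1] / v.sum(axis=1)


def _walk_tree(tree, X: np.ndarray, node_values: np.ndarray) -> tuple:
    n, d = X.shape
    contrib = np.zeros((n, d))
    left, right, feat, thr = tree.children_left, tree.children_right, tree.feature, tree.threshold
    for i in range(n):
        node = 0
        while left[node] != -1:
            f = feat[node]
            nxt = left[node] if X[i, f] <= thr[node] else right[node]
            contrib[i, f] += node_values[nxt] - node_values[node]
            node = nxt
    return contrib, float(node_values[0])


def tree_contributions(model: TrainedModel, X: pd.DataFrame) -> tuple:
    """Per-row additive feature contributions ``(contribs, base)``.

    For decision tree / random forest / extra trees the contributions live in
    probability space: ``base + contribs.sum(axis=1) == predict_proba``.
    For gradient boosting they live in decision-function (log-odds) space:
    ``base + contribs.sum(axis=1) == decision_function``. Raises for
    unsupported estimators (e.g. AdaBoost's weighted vote has no per-path
    additive decomposition here).
    """
    est = model.estimator
    Xv = X[model.feature_names]
    if model.medians:
        Xv = Xv.fillna(model.medians)
    Xv = Xv.values.astype(np.float64)
    if isinstance(est, DecisionTreeClassifier):
        return _walk_tree(est.tree_, Xv, _tree_node_values_classifier(est.tree_))
    if isinstance(est, (RandomForestClassifier, ExtraTreesClassifier)):
        total = np.zeros((Xv.shape[0], Xv.shape[1]))
        base = 0.0
        for sub in est.estimators_:
            c, b = _walk_tree(sub.tree_, Xv, _tree_node_values_classifier(sub.tree_))
            total += c
            base += b
        k = len(est.estimators_)
        return total / k, base / k
    if isinstance(est, GradientBoostingClassifier):
        lr = est.learning_rate
        total = np.zeros((Xv.shape[0], Xv.shape[1]))
        leaf_sum = np.zeros(Xv.shape[0])
        root_sum = 0.0
        for stage in est.estimators_[:, 0]:
            vals = stage.tree_.value.reshape(stage.tree_.node_count)
            c, b = _walk_tree(stage.tree_, Xv, vals)
            total += lr * c
            root_sum += lr * b
            leaf_sum += lr * stage.tree_.value.reshape(-1)[stage.apply(Xv).astype(int)]
        # ensemble offset (prior log-odds) recovered from one decision-function call
        offset = float(est.decision_function(Xv[:1])[0]) - float(leaf_sum[0])
        return total, offset + root_sum
    raise TypeError(
        f"additive tree-path contributions unsupported for {type(est).__name__}"
    )


def importance(model: TrainedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Ranked mean absolute per-feature contribution over the rows of X."""
    contribs, _ = tree_contributions(model, X)
    mean_abs = np.abs(contribs).mean(axis=0)
    out = pd.DataFrame(
        {"feature": model.feature_names, "mean_abs_contribution": mean_abs}
    ).sort_values("mean_abs_contribution", ascending=False, kind="stable")
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Early-warning window
# ---------------------------------------------------------------------------

@dataclass
class EarlyWarningWindow:
    """Hours between each deteriorating case's last evaluated prefix and its
    first deterioration event."""

    windows_hours: dict  # case_id -> hours
    median: float
    q1: float
    q3: float
    n_excluded: int  # positive cases with no retained prefix


def early_warning_window(prefixes: Sequence[Prefix], labels) -> EarlyWarningWindow:
    """Quantify how far in advance predictions are made for deteriorating cases.

    Per positive case the window is the time from the end of its longest
    retained prefix to the first deterioration-defining event; the
    strict-precedence guarantee of prefix generation makes every window
    positive. Positives with no retained prefix are excluded but counted.
    """
    longest: dict = {}
    for p in prefixes:
        if p.case_id not in longest or p.k > longest[p.case_id].k:
            longest[p.case_id] = p
    windows = {}
    n_excluded = 0
    for lab in labels:
        if lab.y != 1:
            continue
        p = longest.get(lab.case_id)
        if p is None:
            n_excluded += 1
            continue
        windows[lab.case_id] = (
            lab.first_deterioration_time - p.end_time
        ).total_seconds() / 3600.0
    vals = np.array(sorted(windows.values()))
    if len(vals):
        q1, med, q3 = (float(np.percentile(vals, q)) for q in (25, 50, 75))
    else:
        q1 = med = q3 = float("nan")
    return EarlyWarningWindow(windows, med, q1, q3, n_excluded)


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Discrimination, calibration and error structure of one model on one test set."""

    algorithm: str
    feature_set: str
    auroc: float
    auprc: float
    brier: float
    prevalence: float
    confusion: ConfusionMatrix
    calibration: pd.DataFrame
    roc_points: pd.DataFrame
    pr_points: pd.DataFrame
    n_test: int

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "feature_set": self.feature_set,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "brier": self.brier,
            "prevalence": self.prevalence,
            "n_test": self.n_test,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
                "threshold": self.confusion.threshold,
                "sensitivity": self.confusion.sensitivity,
                "specificity": self.confusion.specificity,
            },
            # empty bins carry no estimate: represent NaN as None (JSON-safe)
            "calibration": [
                {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in rec.items()}
                for rec in self.calibration.to_dict(orient="records")
            ],
        }


def evaluate(
    model: TrainedModel,
    X_test: pd.DataFrame,
    y_test: Sequence[int],
    threshold: float = 0.5,
    n_bins: int = 10,
) -> EvaluationReport:
    """Score a trained model on held-out prefixes."""
    y = np.asarray(y_test)
    p = model.predict_proba(X_test)
    fpr, tpr, roc_thr = roc_curve(y, p)
    prec, rec, _ = precision_recall_curve(y, p)
    return EvaluationReport(
        algorithm=model.algorithm,
        feature_set=model.feature_set,
        auroc=auroc(y, p),
        auprc=auprc(y, p),
        brier=brier(y, p),
        prevalence=float(y.mean()),
        confusion=confusion(y, p, threshold),
        calibration=calibration(y, p, n_bins),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}),
        pr_points=pd.DataFrame({"precision": prec, "recall": rec}),
        n_test=len(y),
    )
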