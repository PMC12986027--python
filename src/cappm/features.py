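"""Prefix-level feature engineering and matrix assembly.

Feature groups, all computable from the prefix alone (nothing after event k
leaks into a row):

* behavioral — event count, distinct-activity count, revisit ratio
  ``R = 1 - n_distinct / n`` and binary step indicators from a watch list;
* temporal — elapsed hours since the first event, mean inter-event gap,
  hours since the last event;
* clinical — mean/min/max/last of each numeric laboratory attribute observed
  within the prefix (missing until imputation if never observed);
* conformance / trend / declare — produced by the conformance module;
* cluster — unsupervised pathway-cluster membership of the case.

The baseline matrix keeps only behavioral + temporal + clinical columns; the
full matrix adds the conformance, trend, declare and cluster groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .log import DEFAULT_DETERIORATION_SET
from .prefixes import Prefix

#: activities whose presence is flagged with a binary indicator
DEFAULT_WATCH_LIST = (
    "Admission NC",
    "Return ER",
    "IV Antibiotics",
    "IV Liquid",
    "ER Sepsis Triage",
)

#: activities whose occurrence counts enter the pathway-cluster vectors
DEFAULT_CLUSTER_COUNT_ACTIVITIES = (
    "CRP",
    "Leucocytes",
    "LacticAcid",
    "Admission NC",
    "Return ER",
)

BASELINE_GROUPS = ("behavioral", "temporal", "clinical")
CAPPM_ONLY_GROUPS = ("conformance", "trend", "declare", "cluster")
TREND_COLUMNS = ("align_cost_slope", "align_cost_delta")


class AssemblyError(ValueError):
    """A prefix is missing from one of the feature parts."""


def _slug(name: str) -> str:
    return name.replace(" ", "_")


def behavioral_features(prefix: Prefix, watch_list: Sequence[str] = DEFAULT_WATCH_LIST) -> dict:
    """Execution-flow summary of the prefix: n, distinct count, revisit ratio, indicators."""
    acts = prefix.activities()
    n = len(acts)
    if n == 0:
        raise ValueError("prefix must be non-empty")
    distinct = len(set(acts))
    out = {
        "n_events": float(n),
        "n_distinct": float(distinct),
        "revisit_ratio": 1.0 - distinct / n,
    }
    present = set(acts)
    for a in watch_list:
        out[f"seen_{_slug(a)}"] = float(a in present)
    return out


def temporal_features(prefix: Prefix, now_time=None) -> dict:
    """Timing of the prefix in hours: total elapsed, mean gap, time since last event.

    ``now_time`` defaults to the last event's timestamp (offline evaluation),
    making ``hours_since_last_event`` zero. A single-event prefix has mean gap
    0 by convention.
    """
    times = [e.timestamp for e in prefix.events]
    first, last = times[0], times[-1]
    now = now_time if now_time is not None else last
    elapsed = (last - first).total_seconds() / 3600.0
    if len(times) >= 2:
        gaps = [(b - a).total_seconds() / 3600.0 for a, b in zip(times, times[1:])]
        mean_gap = float(np.mean(gaps))
    else:
        mean_gap = 0.0
    return {
        "elapsed_hours": elapsed,
        "mean_inter_event_hours": mean_gap,
        "hours_since_last_event": (now - last).total_seconds() / 3600.0,
    }


def clinical_features(prefix: Prefix, numeric_attrs: Sequence[str]) -> dict:
    """Mean/min/max/last of each numeric attribute observed within the prefix.

    Attributes never observed in the prefix yield NaN in all four aggregates;
    they are median-imputed downstream using training rows only.
    """
    out = {}
    for attr in numeric_attrs:
        values = [
            float(e.attrs[attr])
            for e in prefix.events
            if attr in e.attrs and e.attrs[attr] is not None
        ]
        base = _slug(attr)
        if values:
            out[f"{base}_mean"] = float(np.mean(values))
            out[f"{base}_min"] = float(np.min(values))
            out[f"{base}_max"] = float(np.max(values))
            out[f"{base}_last"] = values[-1]
        else:
            out[f"{base}_mean"] = np.nan
            out[f"{base}_min"] = np.nan
            out[f"{base}_max"] = np.nan
            out[f"{base}_last"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Pathway clustering
# ---------------------------------------------------------------------------

def structural_vectors(
    prefixes_by_case: Mapping[str, Prefix],
    count_activities: Sequence[str] = DEFAULT_CLUSTER_COUNT_ACTIVITIES,
) -> pd.DataFrame:
    """Structural description of each case from its longest retained prefix.

    Columns: prefix length, activity presence indicators over the observed
    alphabet, occurrence counts of selected activities. Built exclusively from
    pre-deterioration events, so clustering never sees post-outcome structure.
    """
    alphabet = sorted(
        {a for p in prefixes_by_case.values() for a in p.activities()}
    )
    rows = {}
    for case_id, p in prefixes_by_case.items():
        acts = p.activities()
        row = {"length": float(len(acts))}
        present = set(acts)
        for a in alphabet:
            row[f"has_{_slug(a)}"] = float(a in present)
        for a in count_activities:
            row[f"count_{_slug(a)}"] = float(acts.count(a))
        rows[case_id] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


class PathwayClusterer(BaseEstimator, ClusterMixin):
    """Unsupervised pathway profiles: z-scoring followed by K-means.

    Fitted without outcome labels; the resulting cluster id is attached to all
    prefixes of a case as a categorical feature. sklearn-compatible
    (``fit``/``predict``/``fit_predict``, ``get_params``/``set_params``).
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) < self.n_clusters:
            raise ValueError(
                f"need at least {self.n_clusters} cases to form {self.n_clusters} clusters"
            )
        self.feature_names_ = list(X.columns)
        self.scaler_ = StandardScaler().fit(X.values)
        self.kmeans_ = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(self.scaler_.transform(X.values))
        self.labels_ = self.kmeans_.labels_
        self.cluster_centers_ = self.kmeans_.cluster_centers_
        return self

    def predict(self, X):
        X = pd.DataFrame(X)[self.feature_names_]
        return self.kmeans_.predict(self.scaler_.transform(X.values))


def fit_pathway_clusters(
    prefixes: Sequence[Prefix],
    n_clusters: int = 3,
    seed: int = 0,
    count_activities: Sequence[str] = DEFAULT_CLUSTER_COUNT_ACTIVITIES,
) -> tuple:
    """Fit pathway clusters on each case's longest retained prefix.

    Returns ``(model, assignment)`` where ``assignment`` maps case id to
    cluster id; the id is broadcast to every prefix of the case downstream.
    """
    longest = longest_prefix_per_case(prefixes)
    X = structural_vectors(longest, count_activities)
    model = PathwayClusterer(n_clusters=n_clusters, random_state=seed).fit(X)
    assignment = dict(zip(X.index, (int(c) for c in model.predict(X))))
    return model, assignment


def longest_prefix_per_case(prefixes: Sequence[Prefix]) -> dict:
    longest: dict = {}
    for p in prefixes:
        if p.case_id not in longest or p.k > longest[p.case_id].k:
            longest[p.case_id] = p
    return longest


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Prefix-level design matrix with its outcome vector and column manifest."""

    X: pd.DataFrame  # indexed by (case_id, k)
    y: pd.Series
    manifest: dict  # column -> feature group
    feature_set: str  # "baseline" | "cappm"

    @property
    def columns(self) -> list:
        return list(self.X.columns)

    def subset(self, case_ids: Iterable[str]) -> "FeatureMatrix":
        ids = set(case_ids)
        mask = self.X.index.get_level_values("case_id").isin(ids)
        return FeatureMatrix(self.X[mask], self.y[mask], self.manifest, self.feature_set)


def prefix_parts(
    prefixes: Sequence[Prefix],
    numeric_attrs: Sequence[str],
    watch_list: Sequence[str] = DEFAULT_WATCH_LIST,
) -> dict:
    """Compute the behavioral, temporal and clinical parts for every prefix."""
    idx = pd.MultiIndex.from_tuples(
        [(p.case_id, p.k) for p in prefixes], names=["case_id", "k"]
    )
    beh = pd.DataFrame([behavioral_features(p, watch_list) for p in prefixes], index=idx)
    tem = pd.DataFrame([temporal_features(p) for p in prefixes], index=idx)
    cli = pd.DataFrame([clinical_features(p, numeric_attrs) for p in prefixes], index=idx)
    return {"behavioral": beh, "temporal": tem, "clinical": cli}


def assemble(
    prefixes: Sequence[Prefix],
    parts: Mapping[str, pd.DataFrame],
    feature_set: str = "cappm",
    deterioration_set: Iterable[str] = DEFAULT_DETERIORATION_SET,
) -> FeatureMatrix:
    """Join feature parts into one matrix with a column->group manifest.

    ``parts`` maps group name to a DataFrame indexed by (case_id, k); the
    ``cluster`` part may instead be indexed by case_id and is broadcast to the
    case's prefixes. Baseline excludes the conformance, trend, declare and
    cluster groups. Raises :class:`AssemblyError` naming the first prefix
    missing from any part, and refuses any column whose name embeds a
    deterioration-defining activity (leakage guard).
    """
    if feature_set not in ("baseline", "cappm"):
        raise ValueError("feature_set must be 'baseline' or 'cappm'")
    keep = BASELINE_GROUPS if feature_set == "baseline" else (
        BASELINE_GROUPS + CAPPM_ONLY_GROUPS
    )
    idx = pd.MultiIndex.from_tuples(
        [(p.case_id, p.k) for p in prefixes], names=["case_id", "k"]
    )
    blocks, manifest = [], {}
    for group in keep:
        if group not in parts:
            if group in CAPPM_ONLY_GROUPS:
                continue  # optional enrichment absent
            raise AssemblyError(f"missing required feature part {group!r}")
        df = parts[group]
        if group == "cluster" and not isinstance(df.index, pd.MultiIndex):
            df = df.reindex(idx.get_level_values("case_id"))
            df.index = idx
        try:
            df = df.loc[idx]
        except KeyError:
            missing = [t for t in idx if t not in df.index][0]
            raise AssemblyError(
                f"part {group!r} missing prefix case={missing[0]!r} k={missing[1]}"
            ) from None
        blocks.append(df)
        for col in df.columns:
            manifest[col] = group
    X = pd.concat(blocks, axis=1)
    guards = [a for a in deterioration_set] + [_slug(a) for a in deterioration_set]
    for col in X.columns:
        if any(g in col for g in guards):
            raise AssemblyError(f"column {col!r} embeds a deterioration-defining activity")
    y = pd.Series([p.y for p in prefixes], index=idx, name="y")
    return FeatureMatrix(X, y, manifest, feature_set)
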