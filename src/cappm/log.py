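"""Event logs: reading, writing, standardization, outcome labelling.

An event log is a set of cases; each case (trace) is the time-ordered sequence
of clinical activities recorded for one patient, annotated with numeric
attributes such as laboratory values. Case outcome is binary: a case counts as
deteriorated when its trace contains a deterioration-defining activity
(by default intensive-care admission ``Admission IC`` or the severe discharge
code ``Release D``).
"""

from __future__ import annotations

import math
import numbers
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Mapping, Sequence

import pandas as pd
from lxml import etree

#: Default set of deterioration-defining activities.
DEFAULT_DETERIORATION_SET = frozenset({"Admission IC", "Release D"})

#: Laboratory attributes treated as time-varying clinical values by default.
DEFAULT_NUMERIC_ATTRS = ("CRP", "Leucocytes", "LacticAcid")

_XES_NS = "http://www.xes-standard.org/"


class SchemaError(ValueError):
    """A mandatory log column/key is missing or malformed."""


@dataclass
class Event:
    """One atomic recorded step of a care pathway."""

    case_id: str
    activity: str
    timestamp: datetime
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.activity:
            raise SchemaError("event has empty activity label")
        if self.timestamp.tzinfo is None:
            self.timestamp = self.timestamp.replace(tzinfo=timezone.utc)
        else:
            self.timestamp = self.timestamp.astimezone(timezone.utc)


@dataclass
class Trace:
    """Time-ordered events of a single case."""

    case_id: str
    events: list

    def __len__(self) -> int:
        return len(self.events)

    def activities(self) -> list:
        return [e.activity for e in self.events]


@dataclass
class EventLog:
    """A collection of traces plus the attribute names treated as clinical numerics."""

    traces: list
    numeric_attrs: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def activity_alphabet(self) -> list:
        seen = {}
        for tr in self.traces:
            for ev in tr.events:
                seen.setdefault(ev.activity, None)
        return sorted(seen)


@dataclass
class OutcomeLabel:
    """Binary case outcome with the position/time of the first deterioration event."""

    case_id: str
    y: int
    first_deterioration_index: int | None = None
    first_deterioration_time: datetime | None = None

    def __post_init__(self) -> None:
        if (self.y == 1) != (self.first_deterioration_index is not None):
            raise ValueError("y=1 iff first_deterioration_index is set")


# ---------------------------------------------------------------------------
# XES I/O
# ---------------------------------------------------------------------------

def _parse_xes_value(elem) -> object:
    tag = etree.QName(elem).localname
    val = elem.get("value")
    if tag == "int":
        return int(val)
    if tag == "float":
        return float(val)
    if tag == "boolean":
        return val.lower() == "true"
    if tag == "date":
        return _parse_timestamp(val)
    return val


def _parse_timestamp(val: str) -> datetime:
    ts = pd.Timestamp(val)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.tz_convert("UTC").to_pydatetime()


def _discover_numeric_attrs(traces: Sequence[Trace], configured: Iterable[str]) -> list:
    """An attribute is clinical-numeric if configured, or numeric/boolean in >=1 event."""
    found: dict = {}
    for tr in traces:
        for ev in tr.events:
            for k, v in ev.attrs.items():
                if isinstance(v, bool) or (
                    isinstance(v, numbers.Number) and not (isinstance(v, float) and math.isnan(v))
                ):
                    found.setdefault(k, None)
    out = list(dict.fromkeys(configured))
    for k in sorted(found):
        if k not in out:
            out.append(k)
    return out


def read_xes(path, numeric_attrs: Iterable[str] = DEFAULT_NUMERIC_ATTRS) -> EventLog:
    """Read an XES file into an :class:`EventLog`.

    Events are sorted by timestamp within each case (stable: original record
    order breaks ties) and timestamps are normalized to UTC. Raises
    :class:`SchemaError` naming the key when a mandatory key
    (``concept:name`` on traces and events, ``time:timestamp`` on events)
    is missing.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    traces: list = []
    for tr_elem in root.iter("{*}trace"):
        attrs = {}
        events = []
        for child in tr_elem:
            tag = etree.QName(child).localname
            if tag == "event":
                ev_attrs = {c.get("key"): _parse_xes_value(c) for c in child if c.get("key")}
                if "concept:name" not in ev_attrs:
                    raise SchemaError("event missing mandatory key 'concept:name'")
                if "time:timestamp" not in ev_attrs:
                    raise SchemaError("event missing mandatory key 'time:timestamp'")
                events.append(ev_attrs)
            elif child.get("key"):
                attrs[child.get("key")] = _parse_xes_value(child)
        if "concept:name" not in attrs:
            raise SchemaError("trace missing mandatory key 'concept:name'")
        case_id = str(attrs["concept:name"])
        evs = []
        for pos, ea in enumerate(events):
            ts = ea["time:timestamp"]
            if not isinstance(ts, datetime):
                try:
                    ts = _parse_timestamp(str(ts))
                except (ValueError, TypeError) as exc:
                    raise SchemaError(
                        f"unparseable timestamp in case {case_id!r} at event {pos}: {ts!r}"
                    ) from exc
            extra = {
                k: v
                for k, v in ea.items()
                if k not in ("concept:name", "time:timestamp", "lifecycle:transition")
            }
            evs.append(Event(case_id, str(ea["concept:name"]), ts, extra))
        evs.sort(key=lambda e: e.timestamp)  # stable: ties keep record order
        traces.append(Trace(case_id, evs))
    _check_unique_cases(traces)
    return EventLog(traces, _discover_numeric_attrs(traces, numeric_attrs))


def write_xes(log: EventLog, path) -> None:
    """Write an :class:`EventLog` as XES 2.0 with deterministic formatting."""
    root = etree.Element("log", nsmap={None: _XES_NS})
    root.set("xes.version", "2.0")
    for tr in log.traces:
        tr_elem = etree.SubElement(root, "trace")
        etree.SubElement(tr_elem, "string", key="concept:name", value=tr.case_id)
        for ev in tr.events:
            ev_elem = etree.SubElement(tr_elem, "event")
            etree.SubElement(ev_elem, "string", key="concept:name", value=ev.activity)
            etree.SubElement(
                ev_elem,
                "date",
                key="time:timestamp",
                value=ev.timestamp.astimezone(timezone.utc).isoformat(),
            )
            for k in sorted(ev.attrs):
                v = ev.attrs[k]
                if isinstance(v, bool):
                    etree.SubElement(ev_elem, "boolean", key=k, value=str(v).lower())
                elif isinstance(v, int):
                    etree.SubElement(ev_elem, "int", key=k, value=str(v))
                elif isinstance(v, float):
                    etree.SubElement(ev_elem, "float", key=k, value=repr(v))
                else:
                    etree.SubElement(ev_elem, "string", key=k, value=str(v))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_csv(
    path,
    column_map: Mapping[str, str],
    numeric_attrs: Iterable[str] = DEFAULT_NUMERIC_ATTRS,
    **pandas_kwargs,
) -> EventLog:
    """Read a CSV event log.

    ``column_map`` must map the keys ``case``, ``activity`` and ``timestamp``
    to column names; every other column becomes an event attribute. Timestamps
    with mixed timezone offsets are normalized to UTC; ties within a case keep
    original row order.
    """
    for key in ("case", "activity", "timestamp"):
        if key not in column_map:
            raise SchemaError(f"column_map missing mandatory mapping for {key!r}")
    df = pd.read_csv(path, **pandas_kwargs)
    for key, col in column_map.items():
        if col not in df.columns:
            raise SchemaError(f"mapped column {col!r} (for {key!r}) not in CSV")
    ccol, acol, tcol = column_map["case"], column_map["activity"], column_map["timestamp"]
    df = df.copy()
    df[tcol] = pd.to_datetime(df[tcol], utc=True, format="mixed")
    other_cols = [c for c in df.columns if c not in (ccol, acol, tcol)]
    traces = []
    for case_id, grp in df.groupby(ccol, sort=False):
        grp = grp.sort_values(tcol, kind="stable")
        evs = []
        for _, row in grp.iterrows():
            attrs = {}
            for c in other_cols:
                v = row[c]
                if isinstance(v, float) and math.isnan(v):
                    continue
                attrs[c] = v
            evs.append(Event(str(case_id), str(row[acol]), row[tcol].to_pydatetime(), attrs))
        traces.append(Trace(str(case_id), evs))
    _check_unique_cases(traces)
    return EventLog(traces, _discover_numeric_attrs(traces, numeric_attrs))


def _check_unique_cases(traces: Sequence[Trace]) -> None:
    seen = set()
    for tr in traces:
        if tr.case_id in seen:
            raise SchemaError(f"duplicate case id {tr.case_id!r}")
        seen.add(tr.case_id)


# ---------------------------------------------------------------------------
# Labelling, imputation, summary statistics
# ---------------------------------------------------------------------------

def label_cases(
    log: EventLog, deterioration_set: Iterable[str] = DEFAULT_DETERIORATION_SET
) -> list:
    """Label every case: y=1 iff the trace contains a deterioration-defining activity.

    Records the index and timestamp of the first such event; the label is a
    case-level property, inherited later by every prefix of the case.
    """
    det = frozenset(deterioration_set)
    if not det:
        raise ValueError("deterioration_set must be non-empty")
    labels = []
    for tr in log.traces:
        idx = next((i for i, e in enumerate(tr.events) if e.activity in det), None)
        if idx is None:
            labels.append(OutcomeLabel(tr.case_id, 0))
        else:
            labels.append(OutcomeLabel(tr.case_id, 1, idx, tr.events[idx].timestamp))
    return labels


def impute_median(
    matrix: pd.DataFrame,
    numeric_columns: Sequence[str],
    train_index=None,
) -> tuple:
    """Median-impute missing numeric values; medians come from training rows only.

    ``train_index`` selects the rows on which medians are computed (all rows if
    omitted, for single-partition use). Returns ``(filled, medians)``. Raises
    ``ValueError`` naming the column if it is entirely missing in training rows.
    """
    out = matrix.copy()
    train = out.loc[train_index] if train_index is not None else out
    medians = {}
    for col in numeric_columns:
        if int(train[col].notna().sum()) == 0:
            raise ValueError(f"column {col!r} has no observed training values to impute from")
        med = train[col].median()
        medians[col] = float(med)
        out[col] = out[col].fillna(med)
    return out, medians


def activity_summary(log: EventLog) -> pd.DataFrame:
    """Per-activity descriptive statistics of occurrence counts across cases.

    For every activity: the number of cases (constant column), then
    mean/std/min/25%/50%/75%/max of its per-case occurrence count, counting 0
    for cases where the activity never occurs. Rows ordered by descending mean.
    """
    acts = log.activity_alphabet()
    counts = pd.DataFrame(
        0, index=[tr.case_id for tr in log.traces], columns=acts, dtype=float
    )
    for tr in log.traces:
        for ev in tr.events:
            counts.at[tr.case_id, ev.activity] += 1
    desc = counts.describe().T
    desc["count"] = float(len(log.traces))
    desc = desc[["count", "mean", "std", "min", "25%", "50%", "75%", "max"]]
    return desc.sort_values("mean", ascending=False)
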