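from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from cappm.log import (
    SchemaError,
    activity_summary,
    impute_median,
    label_cases,
    read_csv,
    read_xes,
    write_xes,
)
from conftest import make_log


def test_xes_round_trip_preserves_structure(tmp_path):
    log = make_log(
        [
            ("c1", ["ER Registration", "ER Triage", "CRP"], None, 1.0,
             [None, None, {"CRP": 120.5}]),
            ("c2", ["ER Registration", "Release A", "Return ER"]),
        ],
        numeric_attrs=["CRP"],
    )
    path = tmp_path / "log.xes"
    write_xes(log, path)
    back = read_xes(path)
    assert len(back) == 2
    assert [len(tr) for tr in back] == [3, 3]
    assert back.traces[0].activities() == ["ER Registration", "ER Triage", "CRP"]
    assert back.traces[0].events[2].attrs["CRP"] == pytest.approx(120.5)
    assert [e.timestamp for e in back.traces[0].events] == [
        e.timestamp for e in log.traces[0].events
    ]


def test_read_xes_sorts_events_by_time(tmp_path):
    log = make_log([("c1", ["A", "B", "C"])])
    # scramble: write events C, A, B by reordering the in-memory trace
    log.traces[0].events = [log.traces[0].events[i] for i in (2, 0, 1)]
    path = tmp_path / "scrambled.xes"
    write_xes(log, path)
    back = read_xes(path)
    assert back.traces[0].activities() == ["A", "B", "C"]


def test_read_xes_missing_mandatory_key_names_it(tmp_path):
    xml = """<?xml version='1.0'?>
    <log xmlns="http://www.xes-standard.org/">
      <trace><string key="concept:name" value="c1"/>
        <event><date key="time:timestamp" value="2024-01-01T00:00:00+00:00"/></event>
      </trace>
    </log>"""
    p = tmp_path / "bad.xes"
    p.write_text(xml)
    with pytest.raises(SchemaError, match="concept:name"):
        read_xes(p)


def test_read_csv_contract(tmp_path):
    csv = tmp_path / "log.csv"
    csv.write_text(
        "case_id,activity,timestamp,CRP\n"
        "c1,ER Registration,2024-01-01T00:00:00+00:00,\n"
        "c1,CRP,2024-01-01T03:00:00+02:00,88.0\n"  # mixed tz offset
        "c1,ER Triage,2024-01-01T01:00:00+00:00,\n"
        "c2,ER Registration,2024-01-01T00:00:00+00:00,\n"
        "c2,ER Triage,2024-01-01T00:00:00+00:00,\n"  # duplicate timestamp: stable order
    )
    log = read_csv(csv, {"case": "case_id", "activity": "activity", "timestamp": "timestamp"})
    assert len(log) == 2
    tr1 = log.traces[0]
    # CRP at 03:00+02:00 normalizes to 01:00 UTC, tying with ER Triage;
    # the tie keeps original row order (CRP row precedes ER Triage row)
    assert tr1.activities() == ["ER Registration", "CRP", "ER Triage"]
    assert all(e.timestamp.tzinfo is not None for e in tr1.events)
    assert tr1.events[1].timestamp == datetime(2024, 1, 1, 1, 0, tzinfo=timezone.utc)
    assert log.traces[1].activities() == ["ER Registration", "ER Triage"]
    with pytest.raises(SchemaError):
        read_csv(csv, {"case": "case_id", "activity": "activity"})


@pytest.mark.parametrize(
    "activities,expected_y,expected_idx",
    [
        (["A"] * 7 + ["Admission IC", "B"], 1, 7),
        (["ER Registration", "Release A"], 0, None),
        (["Release D"], 1, 0),
    ],
)
def test_label_cases(activities, expected_y, expected_idx):
    log = make_log([("c1", activities)])
    (lab,) = label_cases(log)
    assert lab.y == expected_y
    assert lab.first_deterioration_index == expected_idx
    if expected_y:
        assert lab.first_deterioration_time == log.traces[0].events[expected_idx].timestamp
    # idempotence
    (lab2,) = label_cases(log)
    assert lab2 == lab


def test_impute_median_uses_train_rows_only():
    df = pd.DataFrame({"x": [1.0, np.nan, 3.0, np.nan]})
    filled, medians = impute_median(df, ["x"], train_index=[0, 1, 2])
    assert medians["x"] == 2.0  # median of train rows {1, 3}
    assert filled["x"].tolist() == [1.0, 2.0, 3.0, 2.0]
    # identity when nothing missing
    df2 = pd.DataFrame({"x": [1.0, 2.0]})
    filled2, _ = impute_median(df2, ["x"])
    pd.testing.assert_frame_equal(filled2, df2)
    with pytest.raises(ValueError, match="x"):
        impute_median(pd.DataFrame({"x": [np.nan, np.nan]}), ["x"])


def test_activity_summary_matches_brute_force(moderate_log):
    log, _ = moderate_log
    summ = activity_summary(log)
    # brute force: per-case occurrence counts grouped by hand
    acts = log.activity_alphabet()
    for a in ("ER Registration", "CRP", "Admission IC"):
        counts = [tr.activities().count(a) for tr in log.traces]
        assert summ.loc[a, "count"] == len(log)
        assert summ.loc[a, "mean"] == pytest.approx(np.mean(counts))
        assert summ.loc[a, "std"] == pytest.approx(np.std(counts, ddof=1))
        assert summ.loc[a, "50%"] == pytest.approx(np.median(counts))
        assert summ.loc[a, "max"] == max(counts)
    assert set(summ.index) == set(acts)
    # every generated case starts with exactly one ER Registration
    assert summ.loc["ER Registration", "mean"] == 1.0
    assert summ.loc["ER Registration", "std"] == 0.0
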