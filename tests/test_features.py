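import numpy as np
import pandas as pd
import pytest

from cappm.features import (
    AssemblyError,
    PathwayClusterer,
    assemble,
    behavioral_features,
    clinical_features,
    fit_pathway_clusters,
    longest_prefix_per_case,
    prefix_parts,
    structural_vectors,
    temporal_features,
)
from cappm.log import label_cases
from cappm.prefixes import generate_prefixes
from conftest import make_log


def _prefix(activities, attrs_per_event=None, gap_hours=1.0):
    log = make_log([("c1", activities, None, gap_hours, attrs_per_event)])
    return generate_prefixes(log, label_cases(log), [len(activities)])[0]


@pytest.mark.parametrize(
    "acts,n,distinct,R",
    [
        (["A", "B", "C"], 3, 3, 0.0),
        (["A", "B", "A"], 3, 2, 1 / 3),
        (["A", "A", "A", "A"], 4, 1, 0.75),
    ],
)
def test_behavioral_revisit_ratio(acts, n, distinct, R):
    f = behavioral_features(_prefix(acts), watch_list=["A", "Z"])
    assert f["n_events"] == n and f["n_distinct"] == distinct
    assert f["revisit_ratio"] == pytest.approx(R)
    assert 0 <= f["revisit_ratio"] < 1
    assert (f["revisit_ratio"] == 0) == (n == distinct)
    assert f["seen_A"] == 1.0 and f["seen_Z"] == 0.0


def test_temporal_features_hours():
    # three events, gaps 1h and 3h -> elapsed 4h, mean gap 2h
    log = make_log([("c1", ["A", "B", "C"])])
    evs = log.traces[0].events
    from datetime import timedelta

    evs[1].timestamp = evs[0].timestamp + timedelta(hours=1)
    evs[2].timestamp = evs[0].timestamp + timedelta(hours=4)
    p = generate_prefixes(log, label_cases(log), [3])[0]
    f = temporal_features(p)
    assert f["elapsed_hours"] == pytest.approx(4.0)
    assert f["mean_inter_event_hours"] == pytest.approx(2.0)
    assert f["hours_since_last_event"] == 0.0
    f2 = temporal_features(p, now_time=evs[2].timestamp + timedelta(hours=2))
    assert f2["hours_since_last_event"] == pytest.approx(2.0)
    # 7200 s between first and only other event -> 2.0 elapsed hours
    evs[2].timestamp = evs[0].timestamp + timedelta(seconds=7200)
    evs[1].timestamp = evs[0].timestamp + timedelta(seconds=3600)
    assert temporal_features(
        generate_prefixes(log, label_cases(log), [3])[0]
    )["elapsed_hours"] == pytest.approx(2.0)


def test_temporal_features_degenerate():
    p = _prefix(["A"], gap_hours=0.0)
    f = temporal_features(p)
    assert f == {"elapsed_hours": 0.0, "mean_inter_event_hours": 0.0, "hours_since_last_event": 0.0}


def test_clinical_aggregates():
    p = _prefix(
        ["CRP", "X", "CRP"],
        attrs_per_event=[{"CRP": 10.0}, None, {"CRP": 30.0}],
    )
    f = clinical_features(p, ["CRP", "LacticAcid"])
    assert f["CRP_mean"] == 20.0 and f["CRP_min"] == 10.0
    assert f["CRP_max"] == 30.0 and f["CRP_last"] == 30.0
    # attribute never observed: all four aggregates missing pre-imputation
    assert all(np.isnan(f[k]) for k in ("LacticAcid_mean", "LacticAcid_min",
                                        "LacticAcid_max", "LacticAcid_last"))
    p1 = _prefix(["CRP"], attrs_per_event=[{"CRP": 7.0}])
    f1 = clinical_features(p1, ["CRP"])
    assert f1["CRP_mean"] == f1["CRP_min"] == f1["CRP_max"] == f1["CRP_last"] == 7.0


def _two_group_prefixes():
    specs = []
    for i in range(50):
        specs.append((f"g1_{i}", ["A", "B", "C", "D", "E"]))
        specs.append((f"g2_{i}", ["A", "X", "X", "X", "X", "X", "Y", "Z", "W", "Q"]))
    log = make_log(specs)
    return generate_prefixes(log, label_cases(log), [3, 5, 10])


def test_pathway_clusters_recover_separated_groups():
    prefixes = _two_group_prefixes()
    model, assignment = fit_pathway_clusters(prefixes, n_clusters=3, seed=0)
    purity_groups = {}
    for case, cl in assignment.items():
        purity_groups.setdefault(case.split("_")[0], []).append(cl)
    # each true group lands (almost) entirely in one cluster
    for grp, cls in purity_groups.items():
        top = max(set(cls), key=cls.count)
        assert cls.count(top) / len(cls) >= 0.9


def test_clusterer_is_label_blind_and_order_invariant():
    prefixes = _two_group_prefixes()
    _, a1 = fit_pathway_clusters(prefixes, seed=3)
    _, a2 = fit_pathway_clusters(list(reversed(prefixes)), seed=3)
    assert a1 == a2
    # degenerate: identical traces occupy a single cluster
    log = make_log([(f"c{i}", ["A", "B", "C", "D"]) for i in range(10)])
    ps = generate_prefixes(log, label_cases(log), [3])
    _, assign = fit_pathway_clusters(ps, n_clusters=3, seed=0)
    assert len(set(assign.values())) == 1


def test_clusterer_requires_enough_cases():
    log = make_log([("c1", ["A", "B", "C"]), ("c2", ["A", "B", "C"])])
    ps = generate_prefixes(log, label_cases(log), [3])
    with pytest.raises(ValueError, match="clusters"):
        fit_pathway_clusters(ps, n_clusters=3)


def test_structural_vectors_use_longest_prefix_only():
    log = make_log([("c1", ["A", "B", "C", "D", "E", "F"])])
    ps = generate_prefixes(log, label_cases(log), [3, 5])
    longest = longest_prefix_per_case(ps)
    assert longest["c1"].k == 5
    sv = structural_vectors(longest, count_activities=["A"])
    assert sv.loc["c1", "length"] == 5.0
    assert sv.loc["c1", "count_A"] == 1.0


def test_assemble_baseline_subset_and_manifest():
    log = make_log(
        [
            ("c1", ["A", "B", "C", "D", "E"]),
            ("c2", ["A", "B", "B", "C", "C"]),
            ("c3", ["A", "C", "B", "D", "D"]),
        ]
    )
    labels = label_cases(log)
    prefixes = generate_prefixes(log, labels, [3, 5])
    parts = prefix_parts(prefixes, numeric_attrs=[], watch_list=["B"])
    idx = pd.MultiIndex.from_tuples(
        [(p.case_id, p.k) for p in prefixes], names=["case_id", "k"]
    )
    parts["declare"] = pd.DataFrame({"viol_a__b": 0.0}, index=idx)
    parts["cluster"] = pd.DataFrame(
        {"pathway_cluster": [0.0, 1.0, 0.0]}, index=pd.Index(["c1", "c2", "c3"])
    )
    cappm = assemble(prefixes, parts, "cappm")
    base = assemble(prefixes, parts, "baseline")
    assert set(base.columns) < set(cappm.columns)
    assert "pathway_cluster" in cappm.columns and "pathway_cluster" not in base.columns
    # identical rows on shared columns
    pd.testing.assert_frame_equal(base.X, cappm.X[base.columns])
    # manifest covers every column exactly once; no clinical columns here
    # because no numeric attributes were configured
    assert set(cappm.manifest) == set(cappm.columns)
    assert set(cappm.manifest.values()) == {"behavioral", "temporal", "declare", "cluster"}
    # cluster id broadcast to all of the case's prefixes
    assert cappm.X.loc[("c2", 3), "pathway_cluster"] == 1.0
    assert cappm.X.loc[("c2", 5), "pathway_cluster"] == 1.0


def test_assemble_errors():
    log = make_log([("c1", ["A", "B", "C"]), ("c2", ["A", "B", "C"])])
    labels = label_cases(log)
    prefixes = generate_prefixes(log, labels, [3])
    parts = prefix_parts(prefixes, numeric_attrs=[])
    missing = {g: df.iloc[:1] for g, df in parts.items()}
    with pytest.raises(AssemblyError, match="c2"):
        assemble(prefixes, missing, "baseline")
    # leakage guard: a column embedding a deterioration activity is refused
    bad = dict(parts)
    idx = parts["behavioral"].index
    bad["declare"] = pd.DataFrame({"seen_Admission_IC": 0.0}, index=idx)
    with pytest.raises(AssemblyError, match="Admission_IC"):
        assemble(prefixes, bad, "cappm")


def test_pathway_clusterer_sklearn_contract():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 4)))
    m = PathwayClusterer(n_clusters=2, random_state=0)
    assert m.get_params()["n_clusters"] == 2
    m.fit(X)
    labs = m.predict(X)
    assert sorted(set(labs)) == [0, 1] or len(set(labs)) <= 2
    assert (m.fit_predict(X) == m.labels_).all()
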