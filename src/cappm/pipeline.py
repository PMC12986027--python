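"""End-to-end orchestration: log -> prefixes -> model -> features -> evaluation.

Every stage is a pure function of (inputs, config, seed); `run_pipeline` wires
them together and returns a manifest so a run can be reproduced exactly.
Alignments are cached per distinct activity sequence, which makes the
conformance stage cheap on logs with repeated variants.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import alignments as al
from . import features as ft
from . import modeling as md
from .discovery import discover_tree
from .log import DEFAULT_DETERIORATION_SET, EventLog, label_cases
from .petri import PetriNet, tree_to_net, write_pnml
from .prefixes import generate_prefixes, split_cases


@dataclass
class PipelineConfig:
    lengths: tuple = (3, 5, 10)
    deterioration_set: tuple = tuple(sorted(DEFAULT_DETERIORATION_SET))
    test_fraction: float = 0.3
    split_seed: int = 0
    model_seed: int = 0
    cluster_seed: int = 0
    n_clusters: int = 3
    alignment_mode: str = "complete"
    algorithms: tuple = ("gradient_boosting",)
    feature_sets: tuple = ("cappm", "baseline")
    threshold: float = 0.5
    noise_threshold: float = 0.0
    watch_list: tuple = ft.DEFAULT_WATCH_LIST
    constraints: tuple = tuple(
        (c.activation, c.response) for c in al.DEFAULT_RESPONSE_CONSTRAINTS
    )

    def response_constraints(self) -> tuple:
        return tuple(al.ResponseConstraint(a, b) for a, b in self.constraints)


@dataclass
class RunManifest:
    config_hash: str
    config: dict
    n_cases: int
    n_prefixes: int
    n_train_prefixes: int
    n_test_prefixes: int
    timestamp: str
    failed_stage: str | None = None
    outputs: dict = field(default_factory=dict)


def align_prefixes(net: PetriNet, prefixes, mode: str = "complete") -> dict:
    """Optimal alignment for every prefix, cached per distinct activity sequence.

    Returns case_id -> list of (k, Alignment) ordered by k.
    """
    cache: dict = {}
    by_case: dict = {}
    for p in sorted(prefixes, key=lambda p: (p.case_id, p.k)):
        key = tuple(p.activities())
        if key not in cache:
            cache[key] = al.align(net, key, mode=mode)
        by_case.setdefault(p.case_id, []).append((p.k, cache[key]))
    return by_case


def build_feature_matrices(
    log: EventLog, labels, prefixes, net: PetriNet, cfg: PipelineConfig
) -> dict:
    """Both feature matrices (full and baseline) over the same prefixes."""
    parts = ft.prefix_parts(prefixes, log.numeric_attrs, cfg.watch_list)
    aligned = align_prefixes(net, prefixes, cfg.alignment_mode)
    conf = al.conformance_features(aligned)
    parts["conformance"] = conf[["align_cost_raw", "align_cost_log1p", "n_sync", "n_model", "n_log"]]
    parts["trend"] = conf[list(ft.TREND_COLUMNS)]
    idx = pd.MultiIndex.from_tuples(
        [(p.case_id, p.k) for p in prefixes], names=["case_id", "k"]
    )
    parts["declare"] = pd.DataFrame(
        [al.declare_features(p.activities(), cfg.response_constraints()) for p in prefixes],
        index=idx,
    )
    _, assignment = ft.fit_pathway_clusters(
        prefixes, n_clusters=cfg.n_clusters, seed=cfg.cluster_seed
    )
    parts["cluster"] = pd.DataFrame(
        {"pathway_cluster": pd.Series(assignment, dtype=float)}
    )
    det = set(cfg.deterioration_set)
    return {
        fs: ft.assemble(prefixes, parts, feature_set=fs, deterioration_set=det)
        for fs in ("cappm", "baseline")
    }


def run_pipeline(log: EventLog, cfg: PipelineConfig | None = None, out_dir=None) -> dict:
    """Execute the full chain and return reports, models, matrices and a manifest.

    With ``out_dir`` set, persists the reference net (PNML), feature matrices
    (CSV + JSON column manifest), reports (JSON) and the run manifest; on a
    stage failure, artifacts produced so far are kept and the manifest records
    the failed stage.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(cfg)
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        config=cfg_dict,
        n_cases=len(log),
        n_prefixes=0,
        n_train_prefixes=0,
        n_test_prefixes=0,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    result = {"manifest": manifest, "reports": {}, "models": {}, "matrices": None}
    stage = "label"
    try:
        det = set(cfg.deterioration_set)
        labels = label_cases(log, det)
        stage = "prefix"
        prefixes = generate_prefixes(log, labels, cfg.lengths, det)
        manifest.n_prefixes = len(prefixes)
        stage = "split"
        split = split_cases(labels, cfg.test_fraction, cfg.split_seed)
        stage = "discover"
        net = tree_to_net(discover_tree(log, cfg.noise_threshold))
        if out is not None:
            write_pnml(net, out / "reference_net.pnml")
            manifest.outputs["reference_net"] = "reference_net.pnml"
        stage = "features"
        matrices = build_feature_matrices(log, labels, prefixes, net, cfg)
        result["matrices"] = matrices
        stage = "train_evaluate"
        train_ids, test_ids = split.train_case_ids, split.test_case_ids
        numeric_cols_cache: dict = {}
        for fs in cfg.feature_sets:
            fm = matrices[fs]
            tr, te = fm.subset(train_ids), fm.subset(test_ids)
            manifest.n_train_prefixes = len(tr.X)
            manifest.n_test_prefixes = len(te.X)
            from .log import impute_median

            na_cols = [c for c in fm.X.columns if fm.X[c].isna().any()]
            tr_X, medians = impute_median(tr.X, na_cols)
            numeric_cols_cache[fs] = medians
            for algo in cfg.algorithms:
                model = md.train(
                    tr_X, tr.y.values, algo, cfg.model_seed, fs, medians=medians
                )
                report = md.evaluate(model, te.X, te.y.values, cfg.threshold)
                result["models"][(fs, algo)] = model
                result["reports"][(fs, algo)] = report
                if out is not None:
                    name = f"report_{fs}_{algo}.json"
                    (out / name).write_text(json.dumps(report.to_dict(), indent=2))
                    manifest.outputs[f"report_{fs}_{algo}"] = name
            if out is not None:
                fm.X.assign(y=fm.y).to_csv(out / f"features_{fs}.csv")
                (out / f"manifest_{fs}.json").write_text(json.dumps(fm.manifest, indent=2))
        stage = "early_warning"
        result["early_warning"] = md.early_warning_window(prefixes, labels)
        result["labels"], result["prefixes"], result["net"], result["split"] = (
            labels,
            prefixes,
            net,
            split,
        )
    except Exception:
        manifest.failed_stage = stage
        if out is not None:
            (out / "run_manifest.json").write_text(
                json.dumps(asdict(manifest), indent=2, default=str)
            )
        raise
    if out is not None:
        (out / "run_manifest.json").write_text(
            json.dumps(asdict(manifest), indent=2, default=str)
        )
    return result
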