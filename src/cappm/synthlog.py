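"""Ground-truth-known synthetic emergency-care event logs.

The generator emulates the structure of a sepsis-style emergency-department
log: an entry sequence (ER Registration -> ER Triage -> ER Sepsis Triage),
repeated laboratory loops (CRP, Leucocytes, LacticAcid with numeric values),
optional intravenous treatment (IV Liquid then IV Antibiotics), ward admission
loops, possible ER returns, and a final admission/release outcome. Cases that
deteriorate end in Admission IC or Release D, so the outcome-labelling rule
reproduces the generator's ground truth exactly.

Deviation-outcome coupling is configurable per channel and is the knob the
simulation experiments turn: *pathway* coupling injects order violations
(swapped triage steps, antibiotics deferred until after ward admission), extra
laboratory repeats and off-model activities into deteriorating cases, while
*clinical/temporal* coupling shifts laboratory values and slows inter-event
times. With all coupling weights at zero the two classes are generated by an
identical mechanism except for the final outcome activity, so no prefix-level
feature carries signal.

It is not a clinically realistic sepsis simulator: there is no physiology
model, laboratory values are class-conditional lognormals, and inter-event
gaps are exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np

from .log import Event, EventLog, Trace

OFF_MODEL_ACTIVITY = "Unscheduled Imaging"

#: lognormal location/scale per laboratory test (plausible ED magnitudes)
_LAB_PARAMS = {
    "CRP": (np.log(80.0), 0.6),
    "Leucocytes": (np.log(10.0), 0.4),
    "LacticAcid": (np.log(1.8), 0.5),
}


@dataclass
class GeneratorConfig:
    """Synthetic-log study conditions.

    Defaults mirror the real sepsis log's scale: 1050 cases with a 12.3%
    deterioration prevalence, and moderate coupling on both the pathway and the
    clinical/temporal channels (real deterioration expresses through both).
    Probabilities apply to deteriorating cases only.
    """

    n_cases: int = 1050
    prevalence: float = 0.123
    seed: int = 0
    base_gap_hours: float = 1.0
    # pathway (conformance) coupling
    entry_swap_prob: float = 0.35  # ER Triage / ER Sepsis Triage order violation
    delay_antibiotics_prob: float = 0.5  # IV Antibiotics deferred past ward admission
    extra_lab_loop_prob: float = 0.3  # two extra laboratory repeats
    offmodel_insert_prob: float = 0.15  # off-model activity inserted mid-pathway
    # clinical / temporal coupling
    lab_shift: float = 0.4  # added to lognormal location for deteriorators
    delay_multiplier: float = 1.5  # inter-event slowdown for deteriorators
    # share of deteriorating cases whose Admission IC happens right after entry,
    # exercising the prefix-exclusion logic
    early_ic_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases < 10:
            raise ValueError("n_cases must be >= 10")
        for name in (
            "prevalence",
            "entry_swap_prob",
            "delay_antibiotics_prob",
            "extra_lab_loop_prob",
            "offmodel_insert_prob",
            "early_ic_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.delay_multiplier <= 0 or self.base_gap_hours <= 0:
            raise ValueError("rates must be positive")

    @classmethod
    def uncoupled(cls, **kw) -> "GeneratorConfig":
        """Zero deviation-outcome coupling: classes differ only in the final activity."""
        return cls(
            entry_swap_prob=0.0,
            delay_antibiotics_prob=0.0,
            extra_lab_loop_prob=0.0,
            offmodel_insert_prob=0.0,
            lab_shift=0.0,
            delay_multiplier=1.0,
            early_ic_fraction=0.0,
            **kw,
        )

    @classmethod
    def conformance_only(cls, **kw) -> "GeneratorConfig":
        """Pathway-deviation coupling only; clinical and temporal channels silent."""
        return cls(lab_shift=0.0, delay_multiplier=1.0, **kw)


@dataclass
class GroundTruth:
    """Per-case generating truth, consistent with the outcome-labelling rule."""

    labels: dict  # case_id -> 0/1
    deviations: dict = field(default_factory=dict)  # case_id -> injected deviation names
    model_reference: str = "synthetic ED sepsis pathway v1"


def generate(config: GeneratorConfig) -> tuple:
    """Generate ``(EventLog, GroundTruth)``; byte-identical XES given a fixed seed."""
    rng = np.random.default_rng(config.seed)
    t0 = datetime(2024, 1, 1, tzinfo=timezone.utc)
    traces, labels, deviations = [], {}, {}
    for i in range(config.n_cases):
        case_id = f"case_{i:05d}"
        y = int(rng.random() < config.prevalence)
        acts, devs = _build_activities(rng, y, config)
        labels[case_id] = y
        deviations[case_id] = devs
        start = t0 + timedelta(hours=float(i))
        scale = config.base_gap_hours * (config.delay_multiplier if y else 1.0)
        events, t = [], start
        for name in acts:
            attrs = {}
            if name in _LAB_PARAMS:
                mu, sigma = _LAB_PARAMS[name]
                attrs[name] = float(rng.lognormal(mu + y * config.lab_shift, sigma))
            events.append(Event(case_id, name, t, attrs))
            t = t + timedelta(hours=float(rng.exponential(scale)) + 1.0 / 3600.0)
        traces.append(Trace(case_id, events))
    log = EventLog(traces, list(_LAB_PARAMS))
    return log, GroundTruth(labels, deviations)


def _build_activities(rng: np.random.Generator, y: int, cfg: GeneratorConfig) -> tuple:
    devs = []
    entry = ["ER Registration", "ER Triage", "ER Sepsis Triage"]
    if y and rng.random() < cfg.entry_swap_prob:
        entry[1], entry[2] = entry[2], entry[1]
        devs.append("entry_swap")

    # lab-loop volume calibrated to the real log's per-case occurrence means
    # (CRP ~3.1, Leucocytes ~3.2, LacticAcid ~1.4 per case)
    n_labs = 6 + int(rng.poisson(1.5))
    labs = [str(rng.choice(list(_LAB_PARAMS))) for _ in range(n_labs)]
    if y and rng.random() < cfg.extra_lab_loop_prob:
        labs += [str(rng.choice(list(_LAB_PARAMS))) for _ in range(2)]
        devs.append("extra_lab_loop")

    iv, deferred_abx = [], []
    if rng.random() < 0.75:
        iv = ["IV Liquid", "IV Antibiotics"]
        if y and rng.random() < cfg.delay_antibiotics_prob:
            iv = ["IV Liquid"]
            deferred_abx = ["IV Antibiotics"]
            devs.append("delayed_antibiotics")

    admission = ["Admission NC"] * (1 + int(rng.poisson(0.3))) if rng.random() < 0.8 else []
    tail = []
    if rng.random() < 0.28:
        tail = ["Return ER"]

    body = labs + iv + admission + deferred_abx + tail
    if y and rng.random() < cfg.offmodel_insert_prob:
        pos = int(rng.integers(0, len(body) + 1))
        body.insert(pos, OFF_MODEL_ACTIVITY)
        devs.append("off_model_insert")

    if y:
        outcome = ["Admission IC" if rng.random() < 0.8 else "Release D"]
        if rng.random() < cfg.early_ic_fraction:
            # deterioration strikes right after entry; later events still happen
            devs.append("early_ic")
            return tuple(entry + outcome + body + ["Release A"]), devs
    else:
        outcome = [
            str(
                rng.choice(
                    ["Release A", "Release B", "Release C", "Release E"],
                    p=[0.85, 0.08, 0.04, 0.03],
                )
            )
        ]
    return tuple(entry + body + outcome), devs


def summarize(log: EventLog):
    """Per-activity occurrence statistics across cases (descriptive summary table)."""
    from .log import activity_summary

    return activity_summary(log)


def coupling_preset(name: str, **kw) -> GeneratorConfig:
    """Named coupling presets for the CLI: strong, moderate, conformance, none."""
    if name == "none":
        return GeneratorConfig.uncoupled(**kw)
    if name == "conformance":
        return GeneratorConfig.conformance_only(**kw)
    if name == "moderate":
        return GeneratorConfig(**kw)
    if name == "strong":
        base = GeneratorConfig(**kw)
        return replace(
            base,
            entry_swap_prob=0.6,
            delay_antibiotics_prob=0.7,
            extra_lab_loop_prob=0.5,
            offmodel_insert_prob=0.3,
            lab_shift=0.6,
            delay_multiplier=2.0,
        )
    raise ValueError(f"unknown coupling preset {name!r}")
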