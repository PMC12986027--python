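from datetime import datetime, timedelta, timezone

import pytest

from cappm.log import Event, EventLog, Trace


def make_trace(case_id, activities, start=None, gap_hours=1.0, attrs_per_event=None):
    """Build a trace with evenly spaced timestamps (helper for fixtures)."""
    t = start or datetime(2024, 1, 1, tzinfo=timezone.utc)
    events = []
    for i, a in enumerate(activities):
        attrs = {}
        if attrs_per_event:
            attrs = dict(attrs_per_event[i] or {})
        events.append(Event(case_id, a, t + timedelta(hours=gap_hours * i), attrs))
    return Trace(case_id, events)


def make_log(traces_spec, numeric_attrs=()):
    """traces_spec: list of (case_id, activities) or (case_id, activities, attrs)."""
    traces = []
    for spec in traces_spec:
        traces.append(make_trace(*spec))
    return EventLog(traces, list(numeric_attrs))


@pytest.fixture(scope="session")
def moderate_log():
    """One moderately sized synthetic log with default (moderate) coupling."""
    from cappm.synthlog import GeneratorConfig, generate

    return generate(GeneratorConfig(n_cases=300, seed=11))


@pytest.fixture(scope="session")
def pipeline_result(moderate_log):
    """A full pipeline run shared by smoke/integration tests."""
    from cappm.pipeline import PipelineConfig, run_pipeline

    log, _ = moderate_log
    cfg = PipelineConfig(algorithms=("gradient_boosting",))
    return run_pipeline(log, cfg)
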