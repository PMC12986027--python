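"""Alignment-based and declarative conformance checking.

An alignment is a minimum-cost pairing of an observed activity sequence with a
run of the reference net, built from synchronous moves (log and model agree),
model moves (a model step with no log event) and log moves (a logged event the
model forbids). The search is uniform-cost (Dijkstra) over the synchronous
product of the trace and the net; ties prefer synchronous moves so alignments
are deterministic.

Two goal semantics are provided. ``complete`` treats the prefix as a finished
trace: the model must reach its final marking, so missing tail activities are
charged as model moves. ``prefix`` only requires the whole prefix to be
consumed with the model left in a marking from which the final marking is
still reachable; completion is not charged, which is the semantically correct
reading for incomplete, ongoing cases. Both are exposed and tested.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .petri import PetriNet

SYNC, MODEL, LOG = "synchronous", "model", "log"

#: default unit costs: synchronous and silent-model moves are free.
DEFAULT_COSTS = {SYNC: 0.0, MODEL: 1.0, LOG: 1.0, "silent": 0.0}


@dataclass(frozen=True)
class Move:
    kind: str  # synchronous | model | log
    activity: str | None  # None for silent model moves
    cost: float


@dataclass
class Alignment:
    moves: list
    cost: float
    n_sync: int
    n_model: int  # visible model moves only
    n_log: int

    def log_projection(self) -> list:
        """Activities of sync + log moves, in order: reproduces the input prefix."""
        return [m.activity for m in self.moves if m.kind in (SYNC, LOG)]


@dataclass(frozen=True)
class ResponseConstraint:
    """Declarative response rule: if ``activation`` occurs, ``response`` must follow."""

    activation: str
    response: str

    def __post_init__(self) -> None:
        if self.activation == self.response:
            raise ValueError("activation and response must differ")


DEFAULT_RESPONSE_CONSTRAINTS = (
    ResponseConstraint("ER Registration", "ER Triage"),
    ResponseConstraint("ER Triage", "ER Sepsis Triage"),
    ResponseConstraint("ER Sepsis Triage", "IV Antibiotics"),
    ResponseConstraint("ER Sepsis Triage", "LacticAcid"),
)


class InfeasibleAlignmentError(RuntimeError):
    """No alignment goal state is reachable (malformed net)."""


def align(
    net: PetriNet,
    activities: Sequence[str],
    mode: str = "complete",
    costs: Mapping[str, float] = DEFAULT_COSTS,
) -> Alignment:
    """Compute an optimal alignment of an activity sequence against a workflow net.

    Returns a minimum-cost alignment; cost 0 iff the sequence replays on the
    net (under the given mode). Raises :class:`InfeasibleAlignmentError` when
    no goal state exists.
    """
    if mode not in ("complete", "prefix"):
        raise ValueError("mode must be 'complete' or 'prefix'")
    acts = [str(a) for a in activities]
    n = len(acts)
    final = net.final_marking
    reach_cache: dict = {}

    def is_goal(i: int, marking: tuple) -> bool:
        if i != n:
            return False
        if mode == "complete":
            return marking == final
        return _final_reachable(net, marking, reach_cache)

    start = (0, net.initial_marking)
    best: dict = {start: 0.0}
    parent: dict = {start: None}
    counter = 0
    heap = [(0.0, counter, start)]
    while heap:
        cost, _, state = heapq.heappop(heap)
        if cost > best.get(state, math.inf):
            continue
        i, marking = state
        if is_goal(i, marking):
            return _reconstruct(parent, state, cost)
        succs = []
        for t in net.enabled_transitions(marking):
            fired = net.fire(t.tid, marking)
            if i < n and t.label == acts[i]:
                succs.append(((i + 1, fired), costs[SYNC], Move(SYNC, t.label, costs[SYNC])))
            mcost = costs["silent"] if t.is_silent else costs[MODEL]
            succs.append(((i, fired), mcost, Move(MODEL, t.label, mcost)))
        if i < n:
            succs.append(((i + 1, marking), costs[LOG], Move(LOG, acts[i], costs[LOG])))
        for nxt, c, move in succs:
            nc = cost + c
            if nc < best.get(nxt, math.inf):
                best[nxt] = nc
                parent[nxt] = (state, move)
                counter += 1
                heapq.heappush(heap, (nc, counter, nxt))
    raise InfeasibleAlignmentError("no alignment goal state reachable; is the net a workflow net?")


def _reconstruct(parent: dict, state, cost: float) -> Alignment:
    moves = []
    while parent[state] is not None:
        prev, move = parent[state]
        moves.append(move)
        state = prev
    moves.reverse()
    n_sync = sum(1 for m in moves if m.kind == SYNC)
    n_model = sum(1 for m in moves if m.kind == MODEL and m.activity is not None)
    n_log = sum(1 for m in moves if m.kind == LOG)
    return Alignment(moves, cost, n_sync, n_model, n_log)


def _final_reachable(net: PetriNet, marking: tuple, cache: dict) -> bool:
    """Whether the final marking is reachable from ``marking`` by firing any moves."""
    if marking in cache:
        return cache[marking]
    final = net.final_marking
    seen = {marking}
    stack = [marking]
    found = False
    while stack:
        m = stack.pop()
        if m == final or cache.get(m):
            found = True
            break
        for t in net.enabled_transitions(m):
            nxt = net.fire(t.tid, m)
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    if found:
        cache[marking] = True
    else:
        for m in seen:  # nothing visited can reach the final marking either
            cache[m] = False
    return found


# ---------------------------------------------------------------------------
# Conformance feature table
# ---------------------------------------------------------------------------

def log1p_cost(x: float) -> float:
    """Natural-log-plus-one transform applied to alignment costs before modelling."""
    return math.log1p(x)


def conformance_features(alignments_by_case: Mapping[str, Sequence[tuple]]) -> pd.DataFrame:
    """Per-prefix conformance metrics plus per-case trend features.

    ``alignments_by_case`` maps case id to ``(k, Alignment)`` pairs ordered by
    prefix length k. Emits one row per prefix: raw and log1p alignment cost and
    the three move counts, plus two case-level trends broadcast to all of the
    case's prefixes: ``align_cost_slope`` (least-squares slope of log1p cost
    against k; 0 for a single prefix) and ``align_cost_delta`` (last minus
    first log1p cost).
    """
    rows = []
    for case_id, pairs in alignments_by_case.items():
        if not pairs:
            continue
        ks = np.array([k for k, _ in pairs], dtype=float)
        logc = np.array([log1p_cost(a.cost) for _, a in pairs])
        if len(pairs) >= 2:
            slope = float(np.polyfit(ks, logc, 1)[0])
        else:
            slope = 0.0
        delta = float(logc[-1] - logc[0])
        for (k, a), lc in zip(pairs, logc):
            rows.append(
                {
                    "case_id": case_id,
                    "k": int(k),
                    "align_cost_raw": float(a.cost),
                    "align_cost_log1p": float(lc),
                    "n_sync": a.n_sync,
                    "n_model": a.n_model,
                    "n_log": a.n_log,
                    "align_cost_slope": slope,
                    "align_cost_delta": delta,
                }
            )
    return pd.DataFrame(rows).set_index(["case_id", "k"]) if rows else pd.DataFrame(
        columns=["align_cost_raw", "align_cost_log1p", "n_sync", "n_model", "n_log",
                 "align_cost_slope", "align_cost_delta"]
    )


# ---------------------------------------------------------------------------
# Declarative response constraints
# ---------------------------------------------------------------------------

def response_violation_ratio(activities: Sequence[str], constraint: ResponseConstraint) -> float:
    """Fraction of activation occurrences not followed by the response later on.

    Ranges from 0 (no violations, or no activations at all) to 1 (every
    activation unanswered within the sequence).
    """
    acts = list(activities)
    activations = [i for i, a in enumerate(acts) if a == constraint.activation]
    if not activations:
        return 0.0
    unanswered = sum(
        1 for i in activations if constraint.response not in acts[i + 1:]
    )
    return unanswered / len(activations)


def declare_features(
    activities: Sequence[str],
    constraints: Iterable[ResponseConstraint] = DEFAULT_RESPONSE_CONSTRAINTS,
) -> dict:
    """Violation ratio per constraint, with file-safe column names."""
    out = {}
    for c in constraints:
        name = f"viol_{_slug(c.activation)}__{_slug(c.response)}"
        out[name] = response_violation_ratio(activities, c)
    return out


def _slug(name: str) -> str:
    return name.replace(" ", "_")
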