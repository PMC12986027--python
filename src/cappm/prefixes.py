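"""Leakage-free prefix generation and case-level train/test splitting.

A prefix is the first k events of a trace and models an incomplete, ongoing
care pathway. To emulate a real early-warning setting, a prefix is usable for
prediction only if it contains no deterioration-defining event, and for
deteriorating cases only if it ends strictly before the first such event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .log import DEFAULT_DETERIORATION_SET, EventLog, OutcomeLabel

logger = logging.getLogger(__name__)

DEFAULT_PREFIX_LENGTHS = (3, 5, 10)


@dataclass
class Prefix:
    """First-k truncation of a trace, carrying the case outcome label."""

    case_id: str
    k: int
    events: list
    y: int
    end_time: datetime

    def activities(self) -> list:
        return [e.activity for e in self.events]


@dataclass
class CaseSplit:
    """Disjoint case-level partition; prefixes inherit their case's side."""

    train_case_ids: set
    test_case_ids: set
    seed: int
    test_fraction: float

    def __post_init__(self) -> None:
        if self.train_case_ids & self.test_case_ids:
            raise ValueError("train and test case sets overlap")

    def side_of(self, case_id: str) -> str:
        return "test" if case_id in self.test_case_ids else "train"


def generate_prefixes(
    log: EventLog,
    labels: Sequence[OutcomeLabel],
    lengths: Iterable[int] = DEFAULT_PREFIX_LENGTHS,
    deterioration_set: Iterable[str] = DEFAULT_DETERIORATION_SET,
) -> list:
    """Generate fixed-length prefixes, excluding any that leak the outcome.

    For each case and each length k not exceeding the trace length, the first-k
    candidate is emitted unless it contains a deterioration-defining activity;
    for deteriorating cases only prefixes ending strictly before the first
    deterioration event are retained. Cases shorter than min(lengths), and
    positive cases whose deterioration occurs too early to leave any usable
    prefix, contribute nothing (logged).
    """
    lengths = sorted(set(int(k) for k in lengths))
    if not lengths or lengths[0] <= 0:
        raise ValueError("prefix lengths must be positive")
    det = frozenset(deterioration_set)
    by_case = {lab.case_id: lab for lab in labels}
    prefixes: list = []
    n_short = n_no_positive_prefix = 0
    for tr in log.traces:
        lab = by_case[tr.case_id]
        emitted = 0
        for k in lengths:
            if k > len(tr.events):
                break
            head = tr.events[:k]
            if any(e.activity in det for e in head):
                continue
            if lab.y == 1 and k > lab.first_deterioration_index:
                # would not end strictly before the first deterioration event
                continue
            prefixes.append(Prefix(tr.case_id, k, list(head), lab.y, head[-1].timestamp))
            emitted += 1
        if emitted == 0:
            if len(tr.events) < lengths[0]:
                n_short += 1
            elif lab.y == 1:
                n_no_positive_prefix += 1
    if n_short:
        logger.info("%d cases shorter than min prefix length; no prefixes emitted", n_short)
    if n_no_positive_prefix:
        logger.info(
            "%d deteriorating cases deteriorate before the first prefix length; excluded",
            n_no_positive_prefix,
        )
    return prefixes


def split_cases(
    labels: Sequence[OutcomeLabel], test_fraction: float = 0.3, seed: int = 0
) -> CaseSplit:
    """Stratified, seeded case-level split. Deterministic given the seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    case_ids = np.array([lab.case_id for lab in labels])
    y = np.array([lab.y for lab in labels])
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls} has fewer than 2 cases; cannot stratify")
    train_ids, test_ids = train_test_split(
        case_ids, test_size=test_fraction, random_state=seed, stratify=y
    )
    return CaseSplit(set(train_ids), set(test_ids), seed, test_fraction)
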