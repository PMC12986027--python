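"""Process-tree discovery with an inductive-miner-style recursion.

The miner recursively partitions the activity alphabet by searching the
directly-follows graph (DFG) for cuts, in the fixed order exclusive-choice,
sequence, parallel, loop. Base cases map single activities and empty traces to
leaves; when no cut exists the recursion falls through to a flower model (a
loop over an exclusive choice of the alphabet). Every trace of the discovery
log replays on the resulting model at zero alignment cost.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .log import EventLog

SEQUENCE = "sequence"
XOR = "exclusive_choice"
PARALLEL = "parallel"
LOOP = "loop"
ACTIVITY = "activity"
SILENT = "silent"


@dataclass
class ProcessTree:
    """Block-structured process model node.

    ``kind`` is one of activity, silent, sequence, exclusive_choice, parallel,
    loop. Activity nodes are leaves; a loop's first child is the do-part.
    """

    kind: str
    label: str | None = None
    children: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind == ACTIVITY and not self.label:
            raise ValueError("activity node requires a label")
        if self.kind == LOOP and len(self.children) < 2:
            raise ValueError("loop requires a do-part and at least one redo-part")
        if self.kind in (ACTIVITY, SILENT) and self.children:
            raise ValueError("leaf nodes cannot have children")

    def __repr__(self) -> str:  # compact, test-friendly
        if self.kind == ACTIVITY:
            return f"'{self.label}'"
        if self.kind == SILENT:
            return "tau"
        op = {SEQUENCE: "seq", XOR: "xor", PARALLEL: "par", LOOP: "loop"}[self.kind]
        return f"{op}({', '.join(map(repr, self.children))})"


def leaf(label: str) -> ProcessTree:
    return ProcessTree(ACTIVITY, label=label)


def tau() -> ProcessTree:
    return ProcessTree(SILENT)


@dataclass
class DirectlyFollowsGraph:
    """Weighted immediate-succession graph of a log."""

    nodes: list
    edges: dict  # (a, b) -> count of immediate successions
    starts: Counter  # first activities of traces
    ends: Counter  # last activities of traces


def build_dfg(log_or_variants) -> DirectlyFollowsGraph:
    """Build the DFG: edge (a, b) counts immediate a->b successions across traces."""
    variants = _as_variants(log_or_variants)
    edges: Counter = Counter()
    starts: Counter = Counter()
    ends: Counter = Counter()
    nodes: dict = {}
    for var, mult in variants.items():
        for a in var:
            nodes.setdefault(a, None)
        if var:
            starts[var[0]] += mult
            ends[var[-1]] += mult
        for a, b in zip(var, var[1:]):
            edges[(a, b)] += mult
    return DirectlyFollowsGraph(sorted(nodes), dict(edges), starts, ends)


def _as_variants(log_or_variants) -> Counter:
    if isinstance(log_or_variants, Counter):
        return log_or_variants
    if isinstance(log_or_variants, EventLog):
        return Counter(tuple(tr.activities()) for tr in log_or_variants.traces)
    return Counter(tuple(v) for v in log_or_variants)


def discover_tree(log_or_variants, noise_threshold: float = 0.0) -> ProcessTree:
    """Discover a process tree from a log.

    ``noise_threshold`` optionally drops DFG edges rarer than the given
    fraction of the heaviest outgoing edge of their source before cut
    detection (off by default; filtering forfeits the perfect-fitness
    guarantee).
    """
    variants = _as_variants(log_or_variants)
    if not variants:
        raise ValueError("cannot discover a model from an empty log")
    if noise_threshold > 0.0:
        variants = _filter_variants(variants, noise_threshold)
    return _discover(variants)


def _filter_variants(variants: Counter, threshold: float) -> Counter:
    """Drop whole variants whose total frequency share is below ``threshold``."""
    total = sum(variants.values())
    kept = Counter({v: c for v, c in variants.items() if c / total >= threshold})
    return kept if kept else variants


# ---------------------------------------------------------------------------
# Recursion
# ---------------------------------------------------------------------------

def _discover(variants: Counter) -> ProcessTree:
    alphabet = sorted({a for v in variants for a in v})
    if not alphabet:
        return tau()
    if () in variants:
        nonempty = Counter({v: c for v, c in variants.items() if v})
        return ProcessTree(XOR, children=[tau(), _discover(nonempty)])
    if len(alphabet) == 1:
        a = alphabet[0]
        if all(len(v) == 1 for v in variants):
            return leaf(a)
        return ProcessTree(LOOP, children=[leaf(a), tau()])  # a one or more times
    dfg = build_dfg(variants)
    for find, split, kind in (
        (_xor_cut, _xor_split, XOR),
        (_sequence_cut, _sequence_split, SEQUENCE),
        (_parallel_cut, _parallel_split, PARALLEL),
        (_loop_cut, _loop_split, LOOP),
    ):
        groups = find(dfg, alphabet)
        if groups is not None and len(groups) > 1:
            sublogs = split(variants, groups)
            if sublogs is not None:
                return ProcessTree(kind, children=[_discover(s) for s in sublogs])
    # flower fall-through: loop over an exclusive choice of the alphabet
    return ProcessTree(
        LOOP, children=[tau(), ProcessTree(XOR, children=[leaf(a) for a in alphabet])]
    )


def _components(nodes: Sequence[str], und_edges: Iterable[tuple]) -> list:
    """Connected components, each sorted; components ordered by smallest member."""
    adj = {n: set() for n in nodes}
    for a, b in und_edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set = set()
    comps = []
    for n in sorted(nodes):
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(sorted(comp))
    return sorted(comps, key=lambda c: c[0])


# -- exclusive choice -------------------------------------------------------

def _xor_cut(dfg: DirectlyFollowsGraph, alphabet) -> list | None:
    comps = _components(alphabet, dfg.edges)
    return comps if len(comps) > 1 else None


def _xor_split(variants: Counter, groups) -> list:
    member = {a: i for i, g in enumerate(groups) for a in g}
    sublogs = [Counter() for _ in groups]
    for var, mult in variants.items():
        sublogs[member[var[0]]][var] += mult  # a variant lies wholly in one component
    return sublogs


# -- sequence ---------------------------------------------------------------

def _sccs(nodes, edges) -> list:
    """Tarjan strongly connected components (iterative), deterministic order."""
    adj = {n: [] for n in nodes}
    for a, b in edges:
        adj[a].append(b)
    for n in adj:
        adj[n].sort()
    index: dict = {}
    low: dict = {}
    on_stack: set = set()
    stack: list = []
    comps: list = []
    counter = [0]

    for root in sorted(nodes):
        if root in index:
            continue
        work = [(root, 0)]
        while work:
            node, pi = work[-1]
            if pi == 0:
                index[node] = low[node] = counter[0]
                counter[0] += 1
                stack.append(node)
                on_stack.add(node)
            advanced = False
            for i in range(pi, len(adj[node])):
                w = adj[node][i]
                if w not in index:
                    work[-1] = (node, i + 1)
                    work.append((w, 0))
                    advanced = True
                    break
                if w in on_stack:
                    low[node] = min(low[node], index[w])
            if advanced:
                continue
            work.pop()
            if work:
                parent = work[-1][0]
                low[parent] = min(low[parent], low[node])
            if low[node] == index[node]:
                comp = set()
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.add(w)
                    if w == node:
                        break
                comps.append(sorted(comp))
    return comps


def _sequence_cut(dfg: DirectlyFollowsGraph, alphabet) -> list | None:
    groups = [frozenset(c) for c in _sccs(alphabet, dfg.edges)]
    if len(groups) < 2:
        return None
    # reachability between groups via the condensation
    idx = {a: i for i, g in enumerate(groups) for a in g}
    n = len(groups)
    reach = [set() for _ in range(n)]
    gadj = [set() for _ in range(n)]
    for a, b in dfg.edges:
        if idx[a] != idx[b]:
            gadj[idx[a]].add(idx[b])
    for i in range(n):
        stack = list(gadj[i])
        while stack:
            j = stack.pop()
            if j in reach[i]:
                continue
            reach[i].add(j)
            stack.extend(gadj[j])

    # merge pairwise-unreachable groups until the remaining groups form a chain
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    changed = True
    while changed:
        changed = False
        roots = sorted({find(i) for i in range(n)})
        for ii, a in enumerate(roots):
            for b in roots[ii + 1:]:
                fwd = any(
                    find(j) == b for i in range(n) if find(i) == a for j in reach[i]
                )
                bwd = any(
                    find(j) == a for i in range(n) if find(i) == b for j in reach[i]
                )
                if fwd == bwd:  # incomparable (or mutually reachable): merge
                    parent[b] = a
                    changed = True
                    break
            if changed:
                break
    roots = sorted({find(i) for i in range(n)})
    if len(roots) < 2:
        return None
    merged = {r: set() for r in roots}
    for i in range(n):
        merged[find(i)] |= groups[i]
    # total order: root A precedes root B iff some member group of A reaches B
    def precedes(a, b):
        return any(find(j) == b for i in range(n) if find(i) == a for j in reach[i])

    ordered = sorted(roots, key=lambda r: sum(precedes(q, r) for q in roots))
    return [sorted(merged[r]) for r in ordered]


def _sequence_split(variants: Counter, groups) -> list | None:
    member = {a: i for i, g in enumerate(groups) for a in g}
    sublogs = [Counter() for _ in groups]
    for var, mult in variants.items():
        pos = 0
        for gi in range(len(groups)):
            start = pos
            while pos < len(var) and member[var[pos]] == gi:
                pos += 1
            sublogs[gi][var[start:pos]] += mult
        if pos != len(var):  # order violation: cut unusable for this log
            return None
    return sublogs


# -- parallel ---------------------------------------------------------------

def _parallel_cut(dfg: DirectlyFollowsGraph, alphabet) -> list | None:
    edges = set(dfg.edges)
    non_parallel = [
        (a, b)
        for i, a in enumerate(alphabet)
        for b in alphabet[i + 1:]
        if not ((a, b) in edges and (b, a) in edges)
    ]
    comps = _components(alphabet, non_parallel)
    if len(comps) < 2:
        return None
    starts, ends = set(dfg.starts), set(dfg.ends)
    for comp in comps:
        if not (set(comp) & starts) or not (set(comp) & ends):
            return None
    return comps


def _parallel_split(variants: Counter, groups) -> list:
    sublogs = [Counter() for _ in groups]
    member = {a: i for i, g in enumerate(groups) for a in g}
    for var, mult in variants.items():
        proj = [[] for _ in groups]
        for a in var:
            proj[member[a]].append(a)
        for gi, p in enumerate(proj):
            sublogs[gi][tuple(p)] += mult
    return sublogs


# -- loop -------------------------------------------------------------------

def _loop_cut(dfg: DirectlyFollowsGraph, alphabet) -> list | None:
    starts, ends = set(dfg.starts), set(dfg.ends)
    body = set(starts) | set(ends)
    if body == set(alphabet):
        return None
    edges = set(dfg.edges)
    while True:
        rest = [a for a in alphabet if a not in body]
        if not rest:
            return None
        rest_edges = [(a, b) for a, b in edges if a in rest and b in rest]
        comps = _components(rest, rest_edges)
        invalid = None
        for comp in comps:
            cset = set(comp)
            entries = {b for a, b in edges if a in body and b in cset}
            exits = {a for a, b in edges if a in cset and b in body}
            ok = all(a in ends for a, b in edges if a in body and b in cset)
            ok = ok and all(b in starts for a, b in edges if a in cset and b in body)
            # redo boundary nodes must connect to every start / from every end
            ok = ok and all(
                all((a, s) in edges for s in starts) for a in exits
            )
            ok = ok and all(
                all((e, b) in edges for e in ends) for b in entries
            )
            if not ok:
                invalid = cset
                break
        if invalid is None:
            return [sorted(body)] + comps
        body |= invalid


def _loop_split(variants: Counter, groups) -> list | None:
    body = set(groups[0])
    member = {a: i for i, g in enumerate(groups) for a in g}
    sublogs = [Counter() for _ in groups]
    for var, mult in variants.items():
        if var[0] not in body or var[-1] not in body:
            return None
        runs: list = []  # (group index, segment)
        start = 0
        for i in range(1, len(var) + 1):
            if i == len(var) or member[var[i]] != member[var[start]]:
                runs.append((member[var[start]], var[start:i]))
                start = i
        for j, (gi, seg) in enumerate(runs):
            expect_body = j % 2 == 0
            if expect_body != (gi == 0):
                return None  # runs must alternate body, redo, body, ...
            sublogs[gi][seg] += mult
        if runs[-1][0] != 0:
            return None
    return sublogs
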