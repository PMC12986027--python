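"""Independent brute-force oracles used to certify the implementation.

These deliberately avoid the package's search/metric code paths: alignment
optimality is certified by exhaustive enumeration of move sequences, model
language by breadth-first reachability, and AUROC by pairwise concordance
counting.
"""

from __future__ import annotations

import math


def exhaustive_min_alignment_cost(net, seq, mode="complete", max_extra_len=6):
    """Minimum alignment cost by exhaustive search over all move sequences.

    Explores every interleaving of log moves (cost 1), model moves (silent 0 /
    visible 1) and synchronous moves (0) with cost-based pruning and no state
    revisits along a path. Suitable for nets with <= ~10 transitions and
    sequences of <= ~6 events.
    """
    seq = list(seq)
    n = len(seq)
    max_len = n + len(net.transitions) + max_extra_len
    best = [math.inf]
    final = net.final_marking

    def reachable_final(marking):
        seen = {marking}
        stack = [marking]
        while stack:
            m = stack.pop()
            if m == final:
                return True
            for t in net.enabled_transitions(m):
                nxt = net.fire(t.tid, m)
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def goal(i, marking):
        if i != n:
            return False
        return marking == final if mode == "complete" else reachable_final(marking)

    def rec(i, marking, cost, depth, on_path):
        if cost >= best[0] or depth > max_len:
            return
        if goal(i, marking):
            best[0] = cost
            return
        state = (i, marking)
        if state in on_path:
            return
        on_path = on_path | {state}
        if i < n:
            rec(i + 1, marking, cost + 1, depth + 1, on_path)  # log move
        for t in net.enabled_transitions(marking):
            fired = net.fire(t.tid, marking)
            if i < n and t.label == seq[i]:
                rec(i + 1, fired, cost, depth + 1, on_path)  # synchronous
            rec(i, fired, cost + (0 if t.is_silent else 1), depth + 1, on_path)
        return

    rec(0, net.initial_marking, 0, 0, frozenset())
    return best[0]


def enumerate_language(net, max_len):
    """All visible-label sequences of complete net runs up to length ``max_len``."""
    out = set()
    seen = set()
    stack = [(net.initial_marking, ())]
    while stack:
        marking, word = stack.pop()
        if (marking, word) in seen:
            continue
        seen.add((marking, word))
        if marking == net.final_marking:
            out.add(word)
        for t in net.enabled_transitions(marking):
            nxt_word = word if t.is_silent else word + (t.label,)
            if len(nxt_word) <= max_len:
                stack.append((net.fire(t.tid, marking), nxt_word))
    return out


def pairwise_auroc(y, p):
    """AUROC as the tie-corrected probability of correct pairwise ranking."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    s = 0.0
    for a in pos:
        for b in neg:
            s += 1.0 if a > b else (0.5 if a == b else 0.0)
    return s / (len(pos) * len(neg))


def ols_slope(xs, ys):
    """Closed-form least-squares slope."""
    n = len(xs)
    xb = sum(xs) / n
    yb = sum(ys) / n
    num = sum((x - xb) * (y - yb) for x, y in zip(xs, ys))
    den = sum((x - xb) ** 2 for x in xs)
    return num / den
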