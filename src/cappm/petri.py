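"""Workflow Petri nets: compositional translation from process trees, PNML I/O.

A net derived from a process tree is a sound, safe workflow net with a single
source and sink place. Markings are represented as tuples of token counts over
the net's place list, which keeps alignment search fast and general.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from lxml import etree

from . import discovery
from .discovery import ProcessTree


@dataclass(frozen=True)
class Transition:
    tid: str
    label: str | None  # None = silent

    @property
    def is_silent(self) -> bool:
        return self.label is None


@dataclass
class PetriNet:
    places: list  # place names, fixed order
    transitions: list  # Transition objects
    pre: dict  # tid -> tuple of place indices consumed
    post: dict  # tid -> tuple of place indices produced
    initial_marking: tuple = ()
    final_marking: tuple = ()
    _place_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._place_index = {p: i for i, p in enumerate(self.places)}
        if not any(self.initial_marking) or not any(self.final_marking):
            raise ValueError("initial and final markings must be non-empty")

    def marking_of(self, place_counts: dict) -> tuple:
        m = [0] * len(self.places)
        for p, c in place_counts.items():
            m[self._place_index[p]] = c
        return tuple(m)

    def is_enabled(self, tid: str, marking: tuple) -> bool:
        return all(marking[i] > 0 for i in self.pre[tid])

    def fire(self, tid: str, marking: tuple) -> tuple:
        m = list(marking)
        for i in self.pre[tid]:
            m[i] -= 1
        for i in self.post[tid]:
            m[i] += 1
        return tuple(m)

    def enabled_transitions(self, marking: tuple) -> list:
        return [t for t in self.transitions if self.is_enabled(t.tid, marking)]

    def labels(self) -> set:
        return {t.label for t in self.transitions if t.label is not None}


class _Builder:
    def __init__(self) -> None:
        self.places: list = []
        self.transitions: list = []
        self.pre: dict = {}
        self.post: dict = {}
        self._np = 0
        self._nt = 0

    def place(self) -> str:
        name = f"p{self._np}"
        self._np += 1
        self.places.append(name)
        return name

    def transition(self, label: str | None, p_in: Iterable[str], p_out: Iterable[str]) -> str:
        tid = f"t{self._nt}"
        self._nt += 1
        self.transitions.append(Transition(tid, label))
        self.pre[tid] = tuple(p_in)
        self.post[tid] = tuple(p_out)
        return tid


def tree_to_net(tree: ProcessTree) -> PetriNet:
    """Standard compositional process-tree-to-Petri-net translation.

    sequence = place-chained subnets; exclusive choice = children share entry
    and exit places; parallel = silent fork/join transitions; loop = do-part
    between two loop places with redo-parts as back edges and silent
    entry/exit transitions.
    """
    b = _Builder()
    source, sink = b.place(), b.place()
    _build(b, tree, source, sink)
    idx = {p: i for i, p in enumerate(b.places)}
    pre = {t: tuple(idx[p] for p in b.pre[t]) for t in b.pre}
    post = {t: tuple(idx[p] for p in b.post[t]) for t in b.post}
    init = tuple(1 if p == source else 0 for p in b.places)
    final = tuple(1 if p == sink else 0 for p in b.places)
    return PetriNet(b.places, b.transitions, pre, post, init, final)


def _build(b: _Builder, node: ProcessTree, p_in: str, p_out: str) -> None:
    kind = node.kind
    if kind == discovery.ACTIVITY:
        b.transition(node.label, [p_in], [p_out])
    elif kind == discovery.SILENT:
        b.transition(None, [p_in], [p_out])
    elif kind == discovery.SEQUENCE:
        cur = p_in
        for i, child in enumerate(node.children):
            nxt = p_out if i == len(node.children) - 1 else b.place()
            _build(b, child, cur, nxt)
            cur = nxt
    elif kind == discovery.XOR:
        for child in node.children:
            _build(b, child, p_in, p_out)
    elif kind == discovery.PARALLEL:
        ins, outs = [], []
        for _ in node.children:
            ins.append(b.place())
            outs.append(b.place())
        b.transition(None, [p_in], ins)  # fork
        for child, pi, po in zip(node.children, ins, outs):
            _build(b, child, pi, po)
        b.transition(None, outs, [p_out])  # join
    elif kind == discovery.LOOP:
        p1, p2 = b.place(), b.place()
        b.transition(None, [p_in], [p1])  # enter
        _build(b, node.children[0], p1, p2)  # do-part
        for redo in node.children[1:]:
            _build(b, redo, p2, p1)
        b.transition(None, [p2], [p_out])  # exit
    else:  # pragma: no cover - guarded by ProcessTree validation
        raise ValueError(f"unknown tree node kind {kind!r}")


# ---------------------------------------------------------------------------
# PNML / DOT
# ---------------------------------------------------------------------------

_PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"


def write_pnml(net: PetriNet, path) -> None:
    root = etree.Element("pnml", nsmap={None: _PNML_NS})
    netel = etree.SubElement(root, "net", id="net0", type="http://www.pnml.org/version-2009/grammar/ptnet")
    page = etree.SubElement(netel, "page", id="page0")
    init = dict(zip(net.places, net.initial_marking))
    for p in net.places:
        pel = etree.SubElement(page, "place", id=p)
        if init[p]:
            im = etree.SubElement(pel, "initialMarking")
            etree.SubElement(im, "text").text = str(init[p])
    for t in net.transitions:
        tel = etree.SubElement(page, "transition", id=t.tid)
        if t.label is not None:
            nm = etree.SubElement(tel, "name")
            etree.SubElement(nm, "text").text = t.label
    arc_id = 0
    for t in net.transitions:
        for i in net.pre[t.tid]:
            etree.SubElement(page, "arc", id=f"a{arc_id}", source=net.places[i], target=t.tid)
            arc_id += 1
        for i in net.post[t.tid]:
            etree.SubElement(page, "arc", id=f"a{arc_id}", source=t.tid, target=net.places[i])
            arc_id += 1
    fm = etree.SubElement(netel, "finalmarkings")
    mk = etree.SubElement(fm, "marking")
    for p, c in zip(net.places, net.final_marking):
        if c:
            pel = etree.SubElement(mk, "place", idref=p)
            etree.SubElement(pel, "text").text = str(c)
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_pnml(path) -> PetriNet:
    tree = etree.parse(str(path))
    places, transitions = [], []
    init_counts: dict = {}
    labels: dict = {}
    arcs = []
    for el in tree.iter():
        tag = etree.QName(el).localname
        if tag == "place":
            if el.getparent() is not None and etree.QName(el.getparent()).localname == "marking":
                continue
            places.append(el.get("id"))
            im = el.find("{*}initialMarking/{*}text")
            if im is not None:
                init_counts[el.get("id")] = int(im.text)
        elif tag == "transition":
            nm = el.find("{*}name/{*}text")
            labels[el.get("id")] = nm.text if nm is not None else None
            transitions.append(el.get("id"))
        elif tag == "arc":
            arcs.append((el.get("source"), el.get("target")))
    final_counts: dict = {}
    for mel in tree.iter("{*}marking"):
        for pel in mel.iter("{*}place"):
            final_counts[pel.get("idref")] = int(pel.find("{*}text").text)
    idx = {p: i for i, p in enumerate(places)}
    pset = set(places)
    pre = {t: [] for t in transitions}
    post = {t: [] for t in transitions}
    for src, dst in arcs:
        if src in pset:
            pre[dst].append(idx[src])
        else:
            post[src].append(idx[dst])
    net = PetriNet(
        places,
        [Transition(t, labels[t]) for t in transitions],
        {t: tuple(v) for t, v in pre.items()},
        {t: tuple(v) for t, v in post.items()},
        tuple(init_counts.get(p, 0) for p in places),
        tuple(final_counts.get(p, 0) for p in places),
    )
    return net


def to_dot(net: PetriNet) -> str:
    lines = ["digraph net {", "  rankdir=LR;"]
    init = dict(zip(net.places, net.initial_marking))
    for p in net.places:
        mark = ' peripheries=2' if init.get(p) else ""
        lines.append(f'  "{p}" [shape=circle label=""{mark}];')
    for t in net.transitions:
        if t.is_silent:
            lines.append(f'  "{t.tid}" [shape=box style=filled fillcolor=black label=""];')
        else:
            lines.append(f'  "{t.tid}" [shape=box label="{t.label}"];')
    for t in net.transitions:
        for i in net.pre[t.tid]:
            lines.append(f'  "{net.places[i]}" -> "{t.tid}";')
        for i in net.post[t.tid]:
            lines.append(f'  "{t.tid}" -> "{net.places[i]}";')
    lines.append("}")
    return "\n".join(lines)


def tree_to_dot(tree: ProcessTree) -> str:
    lines = ["digraph tree {"]
    counter = [0]

    def walk(node):
        nid = f"n{counter[0]}"
        counter[0] += 1
        label = node.label if node.kind == discovery.ACTIVITY else (
            "tau" if node.kind == discovery.SILENT else node.kind
        )
        lines.append(f'  {nid} [label="{label}"];')
        for child in node.children:
            cid = walk(child)
            lines.append(f"  {nid} -> {cid};")
        return nid

    walk(tree)
    lines.append("}")
    return "\n".join(lines)
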