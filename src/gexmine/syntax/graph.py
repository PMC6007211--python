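"""Dependency-graph data model and noun-phrase yield extraction.

The graph uses a canonical enhanced-dependency label set: ``nsubj``,
``nsubj:pass``, ``obj``, ``det``, ``amod``, ``compound``, ``nummod``,
``advmod``, ``conj``, ``cc``, ``appos``, ``case``, ``mark``, ``punct``,
``parataxis``, ``dep`` and preposition-collapsed nominal modifiers of the
form ``nmod:<prep>``. A compared entity introduced by an entity-separator
phrase ("compared to X", fronted "In comparison to X, ...") carries the
dedicated label ``nmod:es``. Conjunct propagation adds copies of a
coordination head's incoming edges to every conjunct (flagged
``propagated``), so an enhanced graph is a DAG-like graph, not a tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: labels whose dependents belong to the noun phrase built around a head
NP_INTERNAL_LABELS = ("det", "amod", "compound", "nummod", "appos", "conj", "cc", "case", "punct")
#: prepositional complements kept inside the NP yield
NP_COMPLEMENT_LABELS = ("nmod:of", "nmod:with")
#: surface lemmas an NP yield must never cross (entity-separator words)
NP_BARRIER_LEMMAS = frozenset({"than", "compared", "versus", "vs", "vs."})


@dataclass(frozen=True)
class DepNode:
    index: int
    surface: str
    lemma: str  # lowercased
    pos: str  # fine tag: NN, NNS, NNP, JJ, JJR, VB, VBD, VBN, ...

    @property
    def cpos(self) -> str:
        """Coarse POS: first two characters of the fine tag."""
        return self.pos[:2]


@dataclass(frozen=True)
class DepEdge:
    governor: int
    dependent: int
    label: str
    propagated: bool = False

    def __post_init__(self) -> None:
        if self.governor == self.dependent:
            raise ValueError("self-loop edge")
        if not self.label:
            raise ValueError("empty edge label")


@dataclass
class DepGraph:
    nodes: list[DepNode]
    edges: list[DepEdge]
    root: int
    _out: dict[int, list[DepEdge]] = field(default_factory=dict, repr=False)
    _in: dict[int, list[DepEdge]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        idx = {n.index for n in self.nodes}
        for e in self.edges:
            if e.governor not in idx or e.dependent not in idx:
                raise ValueError(f"edge endpoint not a node: {e}")
        self._index()

    def _index(self) -> None:
        self._out = {n.index: [] for n in self.nodes}
        self._in = {n.index: [] for n in self.nodes}
        for e in self.edges:
            self._out[e.governor].append(e)
            self._in[e.dependent].append(e)

    def node(self, i: int) -> DepNode:
        return self.nodes[i]

    def out_edges(self, i: int) -> list[DepEdge]:
        return self._out.get(i, [])

    def in_edges(self, i: int) -> list[DepEdge]:
        return self._in.get(i, [])

    def children(self, i: int, label: str | None = None) -> list[int]:
        return [e.dependent for e in self.out_edges(i) if label is None or e.label == label]

    def has_edge(self, gov: int, dep: int, label: str) -> bool:
        return any(e.dependent == dep and e.label == label for e in self.out_edges(gov))

    def add_edge(self, gov: int, dep: int, label: str, propagated: bool = False) -> None:
        if any(e.dependent == dep and e.label == label for e in self.out_edges(gov)):
            return
        e = DepEdge(gov, dep, label, propagated)
        self.edges.append(e)
        self._out[gov].append(e)
        self._in[dep].append(e)


def np_yield(graph: DepGraph, head: int, exclude: frozenset[int] | set[int] = frozenset()) -> tuple[int, int]:
    """Contiguous token span (half-open, in token indices) of the NP at ``head``.

    Follows NP-internal labels plus of-/with-complements; pronominal heads
    ("that in normal tissues") additionally keep their in-complement so the
    anaphoric sample phrase survives. Clausal material, entity-separator words
    and anything in ``exclude`` never enter the span; the returned span is the
    maximal contiguous run of collected tokens containing the head.
    """
    head_node = graph.node(head)
    follow = NP_INTERNAL_LABELS + NP_COMPLEMENT_LABELS
    if head_node.pos.startswith("PR") or head_node.lemma in {"that", "those"}:
        follow = follow + ("nmod:in",)
    collected: set[int] = set()
    stack = [head]
    while stack:
        cur = stack.pop()
        if cur in collected:
            continue
        collected.add(cur)
        for e in graph.out_edges(cur):
            if e.propagated:
                continue
            if cur == head and e.label in ("case", "mark"):
                continue  # the NP's own outer marker is not part of its yield
            if e.label in follow or (cur != head and e.label in NP_COMPLEMENT_LABELS):
                stack.append(e.dependent)
    collected -= set(exclude)
    collected = {i for i in collected if graph.node(i).lemma not in NP_BARRIER_LEMMAS}
    # maximal contiguous run containing the head
    lo = head
    while lo - 1 in collected:
        lo -= 1
    hi = head
    while hi + 1 in collected:
        hi += 1
    return lo, hi + 1


def span_text(graph: DepGraph, span: tuple[int, int]) -> str:
    from ..util import detokenize

    return detokenize([graph.node(i).surface for i in range(span[0], span[1])])
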