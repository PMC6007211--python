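"""Type A (comparison) and Type B (plain-level) relation extraction.

Type A finds a scale indicator (SI), the compared aspect (CA) and the two
compared entities (CE1, CE2) of a comparative sentence; a candidate CE pair
joined by two plain ``nmod:in`` edges is only accepted when an
entity-separator token actually stands between the entities. Type B finds a
level indicator (LI), expressed aspect (EA) and expressed location (EL), and
flags implicit comparisons (comparative or directional LIs such as
"over-expressed" or "higher" imply an unstated baseline; plain "high"/"low"
do not). A trigger token consumed by a full comparison never also yields a
Type B relation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .lexicon import TriggerLexicons
from .syntax.graph import DepGraph, np_yield
from .syntax.patterns import DepPattern, match

Span = tuple[int, int]


@dataclass(frozen=True)
class TypeARelation:
    si: int
    si_surface: str
    ca: int
    ce1: int
    ce2: int
    ca_span: Span
    ce1_span: Span
    ce2_span: Span
    pattern: str
    entity_hint: int | None = None  # set by conjunction expansion


@dataclass(frozen=True)
class TypeBRelation:
    li: int
    li_surface: str
    ea: int
    el: int
    ea_span: Span
    el_span: Span
    implicit_comparison: bool
    pattern: str
    entity_hint: int | None = None


def _negated(graph: DepGraph, idx: int) -> bool:
    return any(
        graph.node(e.dependent).lemma in {"not", "never", "no"}
        for e in graph.out_edges(idx)
        if e.label == "advmod"
    )


def _es_between(graph: DepGraph, lexicons: TriggerLexicons, lo: int, hi: int) -> bool:
    """Is a complete entity-separator phrase strictly between positions lo/hi?"""
    phrases = sorted((tuple(p.split()) for p in lexicons.separators), key=len, reverse=True)
    surfaces = [graph.node(i).surface.lower() for i in range(lo + 1, hi)]
    for i in range(len(surfaces)):
        for phrase in phrases:
            if tuple(surfaces[i : i + len(phrase)]) == phrase:
                return True
    return False


def _attached_via_es(graph: DepGraph, binding: dict[str, int], ce_var: str) -> bool:
    ce = binding[ce_var]
    return any(e.label == "nmod:es" for e in graph.in_edges(ce))


def extract_type_a(
    graph: DepGraph, lexicons: TriggerLexicons, patterns: list[DepPattern]
) -> list[TypeARelation]:
    if not patterns:
        raise ValueError("empty Type A pattern set")
    candidates: list[TypeARelation] = []
    for pat in patterns:
        for b in match(pat, graph, lexicons):
            si, ca, cex, cey = b["si"], b["ca"], b["cex"], b["cey"]
            pred = b.get("pred", si)
            if _negated(graph, si) or _negated(graph, pred):
                continue
            ex_es = _attached_via_es(graph, b, "cex")
            ey_es = _attached_via_es(graph, b, "cey")
            if ex_es and ey_es:
                continue
            if ey_es:
                ce1, ce2 = cex, cey
            elif ex_es:
                ce1, ce2 = cey, cex
            else:
                ce1, ce2 = sorted((cex, cey))
                if not _es_between(graph, lexicons, ce1, ce2):
                    continue
            candidates.append(
                TypeARelation(
                    si=si,
                    si_surface=graph.node(si).surface,
                    ca=ca,
                    ce1=ce1,
                    ce2=ce2,
                    ca_span=np_yield(graph, ca, exclude={si}),
                    ce1_span=np_yield(graph, ce1),
                    ce2_span=np_yield(graph, ce2),
                    pattern=pat.name,
                )
            )
    return _dedupe_a(candidates)


def _dedupe_a(rels: list[TypeARelation]) -> list[TypeARelation]:
    """One relation per SI token: prefer the CE pair nearest the SI (locality
    tie-break), then stable pattern order; identical (si, ce1, ce2) collapse."""
    best: dict[int, TypeARelation] = {}
    order: dict[int, int] = {}

    def dist(r: TypeARelation) -> int:
        return abs(r.ce1 - r.si) + abs(r.ce2 - r.si)

    for pos, r in enumerate(rels):
        cur = best.get(r.si)
        if cur is None or dist(r) < dist(cur):
            best[r.si] = r
            order[r.si] = pos
    return [best[k] for k in sorted(best, key=lambda k: order[k])]


def extract_type_b(
    graph: DepGraph,
    lexicons: TriggerLexicons,
    patterns: list[DepPattern],
    consumed_triggers: frozenset[int] | set[int] = frozenset(),
) -> list[TypeBRelation]:
    if not patterns:
        raise ValueError("empty Type B pattern set")
    implicit = lexicons.li_implicit_high | lexicons.li_implicit_low
    plain = lexicons.li_plain_high | lexicons.li_plain_low
    candidates: list[TypeBRelation] = []
    for pat in patterns:
        for b in match(pat, graph, lexicons):
            li, ea, el = b["li"], b["ea"], b["el"]
            pred = b.get("pred", li)
            if li in consumed_triggers:
                continue
            if _negated(graph, li) or _negated(graph, pred):
                continue
            lemma = graph.node(li).lemma
            exclude = {li} if lemma in plain else set()
            candidates.append(
                TypeBRelation(
                    li=li,
                    li_surface=graph.node(li).surface,
                    ea=ea,
                    el=el,
                    ea_span=np_yield(graph, ea, exclude=exclude),
                    el_span=np_yield(graph, el),
                    implicit_comparison=lemma in implicit,
                    pattern=pat.name,
                )
            )
    # one relation per (li, ea): the EL nearest the trigger wins
    best: dict[tuple[int, int], TypeBRelation] = {}
    order: dict[tuple[int, int], int] = {}
    for pos, r in enumerate(candidates):
        key = (r.li, r.ea)
        cur = best.get(key)
        if cur is None or abs(r.el - r.li) < abs(cur.el - cur.li):
            best[key] = r
            order[key] = pos
    return [best[k] for k in sorted(best, key=lambda k: order[k])]


def extract_relations(
    graph: DepGraph,
    lexicons: TriggerLexicons,
    patterns: dict[str, list[DepPattern]],
) -> tuple[list[TypeARelation], list[TypeBRelation]]:
    """Both extractors with comparison-takes-precedence semantics."""
    rels_a = extract_type_a(graph, lexicons, patterns["type_a"])
    consumed = {r.si for r in rels_a}
    rels_b = extract_type_b(graph, lexicons, patterns["type_b"], consumed)
    return rels_a, rels_b


def expand_conjunctions(relations: list, graph: DepGraph) -> list:
    """Replicate a relation once per coordinated head inside its CA/EA span.

    "the expression of miR-143 and -195 ..." yields one relation per conjunct,
    with an ``entity_hint`` marking which conjunct each copy speaks about.
    """
    out: list = []
    for rel in relations:
        span = rel.ca_span if isinstance(rel, TypeARelation) else rel.ea_span
        groups: list[list[int]] = []
        for i in range(span[0], span[1]):
            conj = [
                e.dependent
                for e in graph.out_edges(i)
                if e.label == "conj" and not e.propagated and span[0] <= e.dependent < span[1]
            ]
            if conj:
                groups.append([i] + conj)
        if not groups:
            out.append(rel)
            continue
        for head in groups[0]:
            out.append(replace(rel, entity_hint=head))
    return out
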