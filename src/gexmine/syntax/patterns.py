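"""Declarative dependency-pattern matching.

A pattern is a small constraint graph: named variables with predicates over
a node's lemma, POS tag or trigger-lexicon membership, plus labeled edge
constraints between variables (labels are regular expressions over the
canonical label set). ``match`` returns every variable binding that
satisfies all constraints — semantically a subgraph-isomorphism search,
implemented as deterministic backtracking seeded from the most constrained
variable. Patterns load from YAML files so the inventory is editable
without touching code; well-formedness (connectivity, known variables,
known lexicons) is checked at load time, not match time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from ..lexicon import TriggerLexicons
from .graph import DepGraph


class PatternError(ValueError):
    """Raised at pattern-load time for ill-formed patterns."""


@dataclass(frozen=True)
class NodeConstraint:
    lemma: re.Pattern | None = None
    pos: re.Pattern | None = None
    lexicon: str | None = None

    def ok(self, lemma: str, pos: str, lexicons: TriggerLexicons) -> bool:
        if self.lemma is not None and not self.lemma.fullmatch(lemma):
            return False
        if self.pos is not None and not self.pos.fullmatch(pos):
            return False
        if self.lexicon is not None and lemma not in lexicons.resolve(self.lexicon):
            return False
        return True


@dataclass(frozen=True)
class EdgeConstraint:
    governor: str
    dependent: str
    label: re.Pattern


@dataclass
class DepPattern:
    name: str
    family: str
    nodes: dict[str, NodeConstraint]
    edges: list[EdgeConstraint]
    result: tuple[str, ...]
    distinct: list[tuple[str, ...]] = field(default_factory=list)

    def validate(self, lexicons: TriggerLexicons) -> None:
        for e in self.edges:
            for v in (e.governor, e.dependent):
                if v not in self.nodes:
                    raise PatternError(f"{self.name}: edge uses unknown variable {v!r}")
        for v in self.result:
            if v not in self.nodes:
                raise PatternError(f"{self.name}: result variable {v!r} not constrained")
        for group in self.distinct:
            for v in group:
                if v not in self.nodes:
                    raise PatternError(f"{self.name}: distinct uses unknown variable {v!r}")
        for c in self.nodes.values():
            if c.lexicon is not None:
                lexicons.resolve(c.lexicon)  # raises KeyError if unknown
        # connectivity of the constraint graph
        if len(self.nodes) > 1:
            adj: dict[str, set[str]] = {v: set() for v in self.nodes}
            for e in self.edges:
                adj[e.governor].add(e.dependent)
                adj[e.dependent].add(e.governor)
            seen = {next(iter(self.nodes))}
            stack = list(seen)
            while stack:
                for nb in adj[stack.pop()]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if seen != set(self.nodes):
                raise PatternError(f"{self.name}: constraint graph is disconnected")


def match(pattern: DepPattern, graph: DepGraph, lexicons: TriggerLexicons) -> list[dict[str, int]]:
    """All bindings of pattern variables to node indices, deduplicated and
    deterministically ordered by the bound token indices of the result vars."""
    variables = list(pattern.nodes)
    # candidate sets per variable
    cands: dict[str, list[int]] = {}
    for v in variables:
        c = pattern.nodes[v]
        cands[v] = [n.index for n in graph.nodes if c.ok(n.lemma, n.pos, lexicons)]
        if not cands[v]:
            return []
    # order variables: most constrained first, then by connectivity to chosen
    order = sorted(variables, key=lambda v: len(cands[v]))
    edges_by_pair = pattern.edges

    results: list[dict[str, int]] = []
    binding: dict[str, int] = {}

    def consistent(var: str, idx: int) -> bool:
        for grp in pattern.distinct:
            if var in grp:
                for other in grp:
                    if other != var and binding.get(other) == idx:
                        return False
        for e in edges_by_pair:
            g, d = e.governor, e.dependent
            if var == g and d in binding:
                if not _edge_ok(graph, idx, binding[d], e.label):
                    return False
            elif var == d and g in binding:
                if not _edge_ok(graph, binding[g], idx, e.label):
                    return False
        return True

    def backtrack(k: int) -> None:
        if k == len(order):
            results.append(dict(binding))
            return
        var = order[k]
        for idx in cands[var]:
            if consistent(var, idx):
                binding[var] = idx
                backtrack(k + 1)
                del binding[var]

    backtrack(0)
    # dedupe on result-variable projection, deterministic order
    seen: set[tuple[int, ...]] = set()
    out: list[dict[str, int]] = []
    for b in sorted(results, key=lambda b: tuple(b[v] for v in pattern.result)):
        key = tuple(b[v] for v in pattern.result)
        if key not in seen:
            seen.add(key)
            out.append(b)
    return out


def _edge_ok(graph: DepGraph, gov: int, dep: int, label: re.Pattern) -> bool:
    return any(e.dependent == dep and label.fullmatch(e.label) for e in graph.out_edges(gov))


# ------------------------------------------------------------------ loading

def _compile(value: str | None) -> re.Pattern | None:
    return re.compile(value) if value is not None else None


def load_pattern_file(path: str | Path, lexicons: TriggerLexicons) -> list[DepPattern]:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    patterns: list[DepPattern] = []
    for entry in raw or []:
        try:
            nodes = {
                name: NodeConstraint(
                    lemma=_compile(spec.get("lemma")),
                    pos=_compile(spec.get("pos")),
                    lexicon=spec.get("lexicon"),
                )
                for name, spec in (entry.get("nodes") or {}).items()
            }
            edges = [
                EdgeConstraint(g, d, re.compile(lbl))
                for g, d, lbl in (entry.get("edges") or [])
            ]
            pat = DepPattern(
                name=entry["name"],
                family=entry.get("family", entry["name"]),
                nodes=nodes,
                edges=edges,
                result=tuple(entry.get("result") or list(nodes)),
                distinct=[tuple(g) for g in (entry.get("distinct") or [])],
            )
            pat.validate(lexicons)
        except PatternError:
            raise
        except (KeyError, TypeError, re.error) as exc:
            raise PatternError(f"malformed pattern entry in {path}: {exc}") from exc
        patterns.append(pat)
    return patterns


def load_default_patterns(lexicons: TriggerLexicons, directory: str | Path | None = None) -> dict[str, list[DepPattern]]:
    """Load the bundled pattern families: keys 'type_a' and 'type_b'."""
    if directory is None:
        directory = Path(str(resources.files("gexmine").joinpath("data", "patterns")))
    directory = Path(directory)
    out: dict[str, list[DepPattern]] = {}
    for stem in ("type_a", "type_b"):
        p = directory / f"{stem}.yaml"
        out[stem] = load_pattern_file(p, lexicons)
    return out
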