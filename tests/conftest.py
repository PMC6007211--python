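"""Shared fixtures: default configuration, parser, and the independent
brute-force subgraph-match oracle used to validate the pattern engine."""

from __future__ import annotations

import itertools

import pytest

from gexmine.assembly import Pipeline, PipelineConfig
from gexmine.syntax.lextag import tag, tokenize
from gexmine.syntax.patterns import DepPattern


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig.default()


@pytest.fixture(scope="session")
def triggers(config):
    return config.triggers


@pytest.fixture(scope="session")
def patterns(config):
    return config.patterns


@pytest.fixture()
def pipeline(config) -> Pipeline:
    return Pipeline(config)


@pytest.fixture(scope="session")
def parser(config):
    from gexmine.syntax.parser import Parser

    return Parser(config.triggers)


@pytest.fixture(scope="session")
def parse(parser):
    def _parse(sentence: str):
        return parser.parse(tag(tokenize(sentence)))

    return _parse


def brute_force_match(pattern: DepPattern, graph, lexicons) -> list[dict[str, int]]:
    """Exhaustive enumeration over all node assignments — the independent
    oracle for the backtracking matcher. Only usable on small graphs."""
    variables = list(pattern.nodes)
    nodes = [n.index for n in graph.nodes]
    results = []
    for combo in itertools.product(nodes, repeat=len(variables)):
        binding = dict(zip(variables, combo))
        ok = True
        for var, idx in binding.items():
            n = graph.node(idx)
            if not pattern.nodes[var].ok(n.lemma, n.pos, lexicons):
                ok = False
                break
        if not ok:
            continue
        for grp in pattern.distinct:
            vals = [binding[v] for v in grp]
            if len(set(vals)) != len(vals):
                ok = False
                break
        if not ok:
            continue
        for e in pattern.edges:
            gov, dep = binding[e.governor], binding[e.dependent]
            if not any(
                ed.dependent == dep and e.label.fullmatch(ed.label)
                for ed in graph.out_edges(gov)
            ):
                ok = False
                break
        if ok:
            results.append(binding)
    seen: set[tuple[int, ...]] = set()
    out = []
    for b in sorted(results, key=lambda b: tuple(b[v] for v in pattern.result)):
        key = tuple(b[v] for v in pattern.result)
        if key not in seen:
            seen.add(key)
            out.append(b)
    return out
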