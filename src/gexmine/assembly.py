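"""Argument filtering, field extraction and record assembly.

Takes the raw Type A/B relations for an abstract, verifies the argument-type
constraints (the compared aspect must be an expression phrase; compared
entities and expressed locations must be disease samples), extracts the
expressed gene/miRNA and the High/Low level, finds the associated disease —
falling back to abstract context (title, first sentence, investigation and
experiment-setup sentences, conclusion) when the sentence only holds a
generic phrase like "cancer tissues" — classifies the frame of reference,
and emits curatable ``ExpressionRecord`` rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus import Abstract, Sentence, prefilter
from .entities import (
    EntityMention,
    dedupe_overlaps,
    find_abbreviations,
    tag_diseases,
    tag_genes,
    tag_mirnas,
    type_disease_sample,
    type_expression_phrase,
)
from .lexicon import NameLexicon, TriggerLexicons, load_disease_lexicon, load_gene_lexicon, load_triggers
from .records import ExpressionRecord
from .relations import TypeARelation, TypeBRelation, expand_conjunctions, extract_relations
from .syntax.graph import DepGraph, span_text
from .syntax.parser import Parser
from .syntax.patterns import DepPattern, load_default_patterns
from .util import detokenize

log = logging.getLogger("gexmine")

#: precedence order for disease-context inference (configurable)
DEFAULT_CONTEXT_ORDER = ("title", "first", "investigation", "analyzed", "conclusion")


@dataclass
class ReasonEntry:
    pmid: str
    sentence_index: int
    stage: str
    code: str


@dataclass
class PipelineConfig:
    triggers: TriggerLexicons
    gene_lexicon: NameLexicon
    disease_lexicon: NameLexicon
    patterns: dict[str, list[DepPattern]]
    context_order: tuple[str, ...] = DEFAULT_CONTEXT_ORDER
    use_conclusion_context: bool = True

    @classmethod
    def default(
        cls,
        *,
        trigger_path=None,
        gene_path=None,
        disease_path=None,
        pattern_dir=None,
        extended_separators: bool = False,
    ) -> "PipelineConfig":
        triggers = load_triggers(trigger_path, extended_separators=extended_separators)
        return cls(
            triggers=triggers,
            gene_lexicon=load_gene_lexicon(gene_path),
            disease_lexicon=load_disease_lexicon(disease_path),
            patterns=load_default_patterns(triggers, pattern_dir),
        )


# --------------------------------------------------------------- field ops

def filter_by_type(
    relation: TypeARelation | TypeBRelation,
    graph: DepGraph,
    mentions: list[EntityMention],
    lexicons: TriggerLexicons,
) -> tuple[bool, str | None]:
    """Argument-type constraints; returns (ok, reason-code-if-dropped)."""
    if isinstance(relation, TypeARelation):
        if not type_expression_phrase(graph, relation.ca, mentions, lexicons):
            return False, "ca-not-expression"
        if not type_disease_sample(graph, relation.ce1, mentions, lexicons):
            return False, "ce1-not-disease-sample"
        if not type_disease_sample(graph, relation.ce2, mentions, lexicons):
            return False, "ce2-not-disease-sample"
        return True, None
    if not type_expression_phrase(graph, relation.ea, mentions, lexicons):
        return False, "ea-not-expression"
    if not type_disease_sample(graph, relation.el, mentions, lexicons):
        return False, "el-not-disease-sample"
    return True, None


def extract_entities_in_aspect(
    relation: TypeARelation | TypeBRelation, mentions: list[EntityMention]
) -> list[EntityMention]:
    """Gene/miRNA mentions inside the CA/EA span (conjunct hint narrows them)."""
    span = relation.ca_span if isinstance(relation, TypeARelation) else relation.ea_span
    found = [m for m in mentions if m.etype in ("GENE", "MIRNA") and m.within(span)]
    if relation.entity_hint is not None:
        hinted = [m for m in found if m.covers_token(relation.entity_hint)]
        if hinted:
            return hinted
    return found


def normalize_level(lemma: str, lexicons: TriggerLexicons) -> str | None:
    if lemma in lexicons.high_triggers:
        return "High"
    if lemma in lexicons.low_triggers:
        return "Low"
    return None


def classify_frame_of_reference(
    relation: TypeARelation | TypeBRelation,
    graph: DepGraph,
    lexicons: TriggerLexicons,
) -> tuple[str, int | None]:
    """Frame flag plus (Type A) the index of the control CE head, if any."""
    if isinstance(relation, TypeBRelation):
        return ("Control_Implicit" if relation.implicit_comparison else "none"), None
    ctl = lexicons.control_modifiers

    def has_control(span: tuple[int, int]) -> bool:
        return any(graph.node(i).lemma in ctl for i in range(span[0], span[1]))

    c1, c2 = has_control(relation.ce1_span), has_control(relation.ce2_span)
    if c1 and c2:
        return "Not_Control", None  # ambiguous: both sides look like baselines
    if c1:
        return "Control", relation.ce1
    if c2:
        return "Control", relation.ce2
    return "Not_Control", None


# ------------------------------------------------------- context inference

def _sentence_mentions(mentions_by_sentence, idx) -> list[EntityMention]:
    return mentions_by_sentence.get(idx, [])


def _first_disease(mentions: list[EntityMention]) -> EntityMention | None:
    ds = [m for m in mentions if m.etype == "DISEASE" and m.norm_id]
    return min(ds, key=lambda m: m.start) if ds else None


def _is_passive_trigger(tokens, i) -> bool:
    if tokens[i].pos != "VBN":
        return False
    return any(tokens[j].lemma == "be" for j in range(max(0, i - 3), i))


def investigation_sentence(sentence: Sentence, lexicons: TriggerLexicons) -> bool:
    """Sentence announcing the investigational aim: an investigation trigger
    whose agent is an author/purpose word, or which stands in the passive."""
    toks = sentence.tokens
    for i, t in enumerate(toks):
        if t.lemma not in lexicons.investigation_triggers:
            continue
        before = {x.lemma for x in toks[:i]}
        if before & set(lexicons.agent_words) or before & set(lexicons.purpose_words):
            return True
        if _is_passive_trigger(toks, i):
            return True
    return False


def analyzed_sentence(sentence: Sentence, lexicons: TriggerLexicons) -> bool:
    """Experiment-setup sentence: passive analyzed-trigger whose theme carries
    a count of patients/samples ("A total of 140 patients ... were enrolled")."""
    toks = sentence.tokens
    for i, t in enumerate(toks):
        if t.lemma not in lexicons.analyzed_triggers:
            continue
        if not _is_passive_trigger(toks, i):
            continue
        if any(x.pos == "CD" for x in toks[:i]):
            return True
    return False


def infer_disease_from_context(
    abstract: Abstract,
    mentions_by_sentence: dict[int, list[EntityMention]],
    lexicons: TriggerLexicons,
    order: tuple[str, ...] = DEFAULT_CONTEXT_ORDER,
    use_conclusion: bool = True,
) -> tuple[str, str, str] | None:
    """(disease_text, doid, source) inferred from qualifying locations.

    Candidates are collected per location class in precedence order; the most
    frequent DOID across qualifying sentences wins, ties broken by precedence
    then by offset.
    """
    sentences = abstract.sentences
    n = len(sentences)
    candidates: list[tuple[int, int, int, EntityMention, str]] = []
    for rank, source in enumerate(order):
        if source == "conclusion" and not use_conclusion:
            continue
        idxs: list[int] = []
        if source == "title":
            idxs = [0]
        elif source == "first":
            idxs = [1] if n > 1 else []
        elif source == "investigation":
            idxs = [i for i in range(1, n) if investigation_sentence(sentences[i], lexicons)]
        elif source == "analyzed":
            idxs = [i for i in range(1, n) if analyzed_sentence(sentences[i], lexicons)]
        elif source == "conclusion":
            idxs = [i for i in range(max(1, n - 2), n)]
        for i in idxs:
            m = _first_disease(_sentence_mentions(mentions_by_sentence, i))
            if m is not None:
                candidates.append((rank, i, m.start, m, source))
    if not candidates:
        return None
    counts: dict[str, int] = {}
    for _, _, _, m, _ in candidates:
        counts[m.norm_id] = counts.get(m.norm_id, 0) + 1
    best = sorted(candidates, key=lambda c: (-counts[c[3].norm_id], c[0], c[1], c[2]))[0]
    _, _, _, mention, source = best
    return mention.surface, mention.norm_id, source


# ------------------------------------------------------------ span rendering

_DETS = {"the", "a", "an"}


def render_sample(graph: DepGraph, span: tuple[int, int], abbreviations: dict[str, str]) -> str:
    """Curator-facing sample string: leading determiners dropped and a
    parenthetically defined long form collapsed to its short form
    ("Oral Squamous Cell Carcinoma (OSCC) tissues" -> "OSCC tissues")."""
    toks = [graph.node(i).surface for i in range(span[0], span[1])]
    while toks and toks[0].lower() in _DETS:
        toks = toks[1:]
    for j, t in enumerate(toks):
        if t in abbreviations and j >= 2 and toks[j - 1] == "(" and j + 1 < len(toks) and toks[j + 1] == ")":
            # drop long form + parens, keep the short form
            toks = [t] + toks[j + 2 :]
            break
    return detokenize(toks)


def extract_disease(
    relation: TypeARelation | TypeBRelation,
    graph: DepGraph,
    mentions: list[EntityMention],
    abstract: Abstract,
    mentions_by_sentence: dict[int, list[EntityMention]],
    lexicons: TriggerLexicons,
    frame: str,
    control_ce: int | None,
    order: tuple[str, ...] = DEFAULT_CONTEXT_ORDER,
    use_conclusion: bool = True,
) -> tuple[str | None, str | None, str | None]:
    """(disease_text, doid, source) for one relation.

    Type A reads the disease from the non-control compared entity; if the
    sentence span only holds generic wording the context inference runs.
    """
    if isinstance(relation, TypeARelation):
        if control_ce is not None and control_ce == relation.ce1:
            disease_span = relation.ce2_span
        else:
            disease_span = relation.ce1_span
    else:
        disease_span = relation.el_span
    inside = [
        m
        for m in mentions
        if m.etype == "DISEASE" and m.norm_id and m.within(disease_span)
    ]
    if inside:
        m = min(inside, key=lambda m: m.tok_start)
        return m.surface, m.norm_id, "sentence"
    ctx = infer_disease_from_context(
        abstract, mentions_by_sentence, lexicons, order=order, use_conclusion=use_conclusion
    )
    if ctx is not None:
        return ctx
    return None, None, None


# ----------------------------------------------------------------- pipeline

class Pipeline:
    """End-to-end extraction over abstracts."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig.default()
        self.parser = Parser(self.config.triggers)
        self.reasons: list[ReasonEntry] = []
        self.counters: dict[str, int] = {}

    def _count(self, key: str, n: int = 1) -> None:
        self.counters[key] = self.counters.get(key, 0) + n

    # -- entity layer ----------------------------------------------------
    def tag_abstract(self, abstract: Abstract) -> dict[int, list[EntityMention]]:
        cfg = self.config
        abbrevs = find_abbreviations(
            [s.tokens for s in abstract.sentences], cfg.disease_lexicon
        )
        out: dict[int, list[EntityMention]] = {}
        for s in abstract.sentences:
            mir = tag_mirnas(s.index, s.tokens)
            genes = tag_genes(s.index, s.tokens, cfg.gene_lexicon, mir)
            diseases = tag_diseases(s.index, s.tokens, cfg.disease_lexicon, abbrevs)
            out[s.index] = dedupe_overlaps(mir + genes + diseases)
        self._abbrevs = abbrevs
        return out

    # -- per-abstract ----------------------------------------------------
    def assemble(self, abstract: Abstract) -> list[ExpressionRecord]:
        cfg = self.config
        mentions_by_sentence = self.tag_abstract(abstract)
        records: list[ExpressionRecord] = []
        for sent in abstract.sentences:
            if not prefilter(sent, cfg.triggers):
                self._count("sentences_prefiltered_out")
                continue
            self._count("sentences_parsed")
            try:
                graph = self.parser.parse(sent.tokens)
            except Exception as exc:  # parsing must never kill an abstract
                log.warning("PMID %s sentence %d: parse failed (%s)", abstract.pmid, sent.index, exc)
                self.reasons.append(ReasonEntry(abstract.pmid, sent.index, "parse", "parser-error"))
                continue
            mentions = mentions_by_sentence.get(sent.index, [])
            rels_a, rels_b = extract_relations(graph, cfg.triggers, cfg.patterns)
            self._count("relations_type_a", len(rels_a))
            self._count("relations_type_b", len(rels_b))
            rels = expand_conjunctions(list(rels_a), graph) + expand_conjunctions(list(rels_b), graph)
            for rel in rels:
                records.extend(
                    self._build_records(rel, graph, sent, abstract, mentions, mentions_by_sentence)
                )
        records.sort(key=lambda r: (r.pmid, r.sentence_index, r.entity_text))
        return records

    def _build_records(
        self, rel, graph, sent, abstract, mentions, mentions_by_sentence
    ) -> list[ExpressionRecord]:
        cfg = self.config
        pmid = abstract.pmid
        ok, code = filter_by_type(rel, graph, mentions, cfg.triggers)
        if not ok:
            self.reasons.append(ReasonEntry(pmid, sent.index, "type-filter", code))
            return []
        is_a = isinstance(rel, TypeARelation)
        trigger = graph.node(rel.si if is_a else rel.li)
        level = normalize_level(trigger.lemma, cfg.triggers)
        if level is None:
            self.reasons.append(ReasonEntry(pmid, sent.index, "level", "unknown-trigger"))
            return []
        entity_mentions = extract_entities_in_aspect(rel, mentions)
        if not entity_mentions:
            self.reasons.append(ReasonEntry(pmid, sent.index, "gene", "no-expressed-entity"))
            return []
        frame, control_ce = classify_frame_of_reference(rel, graph, cfg.triggers)
        disease_text, doid, source = extract_disease(
            rel,
            graph,
            mentions,
            abstract,
            mentions_by_sentence,
            cfg.triggers,
            frame,
            control_ce,
            order=cfg.context_order,
            use_conclusion=cfg.use_conclusion_context,
        )
        if doid is None:
            self.reasons.append(ReasonEntry(pmid, sent.index, "disease", "unresolved-disease"))
        abbrevs = getattr(self, "_abbrevs", {})
        if is_a:
            if control_ce == rel.ce1:
                sample_span, compared_span = rel.ce2_span, rel.ce1_span
            else:
                sample_span, compared_span = rel.ce1_span, rel.ce2_span
            disease_sample = render_sample(graph, sample_span, abbrevs)
            compared_sample = render_sample(graph, compared_span, abbrevs)
        else:
            disease_sample = render_sample(graph, rel.el_span, abbrevs)
            compared_sample = None
        out: list[ExpressionRecord] = []
        for em in entity_mentions:
            out.append(
                ExpressionRecord(
                    pmid=pmid,
                    sentence_index=sent.index,
                    sentence_text=sent.text,
                    relation_type="A" if is_a else "B",
                    entity_text=em.surface,
                    entity_kind="mirna" if em.etype == "MIRNA" else "gene",
                    gene_id=em.norm_id if em.etype == "GENE" else None,
                    mirna_norm=em.norm_id if em.etype == "MIRNA" else None,
                    level=level,
                    disease_text=disease_text,
                    doid=doid,
                    disease_sample=disease_sample,
                    compared_sample=compared_sample,
                    frame_of_reference=frame,
                    disease_source=source,
                )
            )
            self._count(f"records_frame_{frame}")
        return out

    def run(self, abstracts: list[Abstract]) -> list[ExpressionRecord]:
        out: list[ExpressionRecord] = []
        for a in abstracts:
            out.extend(self.assemble(a))
        return out


def assemble(abstract: Abstract, config: PipelineConfig | None = None) -> list[ExpressionRecord]:
    """One-shot convenience wrapper around :class:`Pipeline`."""
    return Pipeline(config).assemble(abstract)
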