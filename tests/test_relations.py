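"""Relation extraction: comparison and plain-level constructions."""

import re

import pytest

from gexmine.relations import expand_conjunctions, extract_relations, extract_type_a, extract_type_b
from gexmine.syntax.graph import span_text
from gexmine.syntax.lextag import tag, tokenize

# The seven comparative benchmark sentences with their expected components
# (comparisons are case- and determiner-insensitive).
COMPARATIVE = [
    (
        "Plasma miR-187 was significantly higher in OSCC patients than in normal individuals.",
        ("higher", "plasma mir-187", "oscc patients", "normal individuals"),
    ),
    (
        "miR-181a expression was lower in HepG2 cells compared to Hep3B cells.",
        ("lower", "mir-181a expression", "hepg2 cells", "hep3b cells"),
    ),
    (
        "miR-95 levels were increased in human prostate cancer specimens compared with normal tissues.",
        ("increased", "mir-95 levels", "human prostate cancer specimens", "normal tissues"),
    ),
    (
        "Higher miR-210 expression was found in metastatic tumors compared to primary tumors.",
        ("higher", "mir-210 expression", "metastatic tumors", "primary tumors"),
    ),
    (
        "Increased TP expression was observed in ovarian cancers than in normal ovaries.",
        ("increased", "tp expression", "ovarian cancers", "normal ovaries"),
    ),
    (
        "In comparison to normal brain tissues, FOXD3 expression was significantly decreased in HGG tissues at both mRNA and protein levels.",
        ("decreased", "foxd3 expression", "hgg tissues", "normal brain tissues"),
    ),
    (
        "Compared to controls, patients with CLL presented a lower expression level of PTEN mRNA (P < 0.001).",
        ("lower", "expression level of pten mrna", "patients with cll", "controls"),
    ),
]

# The six plain-level benchmark sentences: (LI, EA, EL, implicit-comparison).
PLAIN_LEVEL = [
    (
        "GALNT2 is frequently over-expressed in OSCC, especially in the carcinoma cells at the invasive front.",
        ("over-expressed", "galnt2", "oscc", True),
    ),
    (
        "IGF1R expression levels were higher in the right adrenocortical tumor.",
        ("higher", "igf1r expression levels", "right adrenocortical tumor", True),
    ),
    (
        "The levels of miR-373 expression were low in pancreatic cancer cell lines.",
        ("low", "levels of mir-373 expression", "pancreatic cancer cell lines", False),
    ),
    (
        "Higher level of BRF2 expression was found in NSCLC tissues.",
        ("higher", "higher level of brf2 expression", "nsclc tissues", True),
    ),
    (
        "High TRIM32 expression levels were detected in gastric cancer tissues.",
        ("high", "trim32 expression levels", "gastric cancer tissues", False),
    ),
    (
        "We found high expression levels of FKBP51 in melanoma cells.",
        ("high", "expression levels of fkbp51", "melanoma cells", False),
    ),
]


def norm(text: str) -> str:
    text = text.lower().strip()
    text = re.sub(r"^(the|a|an)\s+", "", text)
    return re.sub(r"\s+", " ", text)


class TestTypeA:
    @pytest.mark.parametrize("sentence,expected", COMPARATIVE, ids=[f"cmp{i}" for i in range(1, 8)])
    def test_comparative_components(self, parse, triggers, patterns, sentence, expected):
        g = parse(sentence)
        rels = extract_type_a(g, triggers, patterns["type_a"])
        assert len(rels) == 1, sentence
        r = rels[0]
        got = (
            norm(r.si_surface),
            norm(span_text(g, r.ca_span)),
            norm(span_text(g, r.ce1_span)),
            norm(span_text(g, r.ce2_span)),
        )
        assert got == expected

    def test_no_ce_pair_means_no_comparison(self, parse, triggers, patterns):
        g = parse("The most differently expressed microRNA was miR-224.")
        assert extract_type_a(g, triggers, patterns["type_a"]) == []

    def test_negated_comparison_dropped(self, parse, triggers, patterns):
        g = parse("miR-21 expression was not higher in tumor tissues than in normal tissues.")
        assert extract_type_a(g, triggers, patterns["type_a"]) == []

    def test_empty_pattern_set_is_a_configuration_error(self, parse, triggers):
        g = parse("Expression was higher in tumors than in controls.")
        with pytest.raises(ValueError):
            extract_type_a(g, triggers, [])


class TestTypeB:
    @pytest.mark.parametrize("sentence,expected", PLAIN_LEVEL, ids=[f"lvl{i}" for i in range(1, 7)])
    def test_plain_level_components(self, parse, triggers, patterns, sentence, expected):
        g = parse(sentence)
        rels = extract_type_b(g, triggers, patterns["type_b"])
        assert len(rels) == 1, sentence
        r = rels[0]
        got = (
            norm(r.li_surface),
            norm(span_text(g, r.ea_span)),
            norm(span_text(g, r.el_span)),
            r.implicit_comparison,
        )
        assert got == expected


class TestTriggerClosedWorld:
    def test_all_triggers_from_lexicon(self, parse, triggers, patterns):
        all_si_li = triggers.scale_indicators | triggers.level_indicators
        for sentence, _ in COMPARATIVE + PLAIN_LEVEL:
            g = parse(sentence)
            ra, rb = extract_relations(g, triggers, patterns)
            for r in ra:
                assert g.node(r.si).lemma in all_si_li
            for r in rb:
                assert g.node(r.li).lemma in all_si_li

    def test_type_a_and_b_never_share_a_trigger_token(self, parse, triggers, patterns):
        for sentence, _ in COMPARATIVE + PLAIN_LEVEL:
            g = parse(sentence)
            ra, rb = extract_relations(g, triggers, patterns)
            assert {r.si for r in ra}.isdisjoint({r.li for r in rb})

    def test_comparison_takes_precedence(self, parse, triggers, patterns):
        # same trigger lemma: with a separator it is a comparison, without it
        # falls through to an implicit-comparison plain-level relation
        g1 = parse("miR-21 was over-expressed in tumor tissues compared with normal tissues.")
        ra, rb = extract_relations(g1, triggers, patterns)
        assert len(ra) == 1 and rb == []
        g2 = parse("miR-21 was over-expressed in tumor tissues.")
        ra, rb = extract_relations(g2, triggers, patterns)
        assert ra == [] and len(rb) == 1 and rb[0].implicit_comparison


class TestConjunctionExpansion:
    def test_two_way(self, parse, triggers, patterns):
        g = parse(
            "Conversely, the expression of miR-143 and -195 in cancer tissues was significantly lower compared to that in normal tissues."
        )
        ra = extract_type_a(g, triggers, patterns["type_a"])
        assert len(ra) == 1
        expanded = expand_conjunctions(list(ra), g)
        assert len(expanded) == 2
        assert len({r.entity_hint for r in expanded}) == 2

    def test_three_way(self, parse, triggers, patterns):
        g = parse(
            "The expression of miR-21, miR-155 and miR-143 in cancer tissues was significantly lower than that in normal tissues."
        )
        ra = extract_type_a(g, triggers, patterns["type_a"])
        expanded = expand_conjunctions(list(ra), g)
        assert len(expanded) == 3

    def test_identity_without_coordination(self, parse, triggers, patterns):
        g = parse("miR-181a expression was lower in HepG2 cells compared to Hep3B cells.")
        ra = extract_type_a(g, triggers, patterns["type_a"])
        assert expand_conjunctions(list(ra), g) == ra
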