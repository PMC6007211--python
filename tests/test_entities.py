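"""Entity detection: miRNA regexes, lexicon taggers, abbreviations, typing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gexmine.entities import (
    EntityMention,
    dedupe_overlaps,
    find_abbreviations,
    mirna_norm,
    read_pubtator_annotations,
    tag_diseases,
    tag_genes,
    tag_mirnas,
    type_disease_sample,
    type_expression_phrase,
)
from gexmine.lexicon import NameLexicon, load_disease_lexicon, load_gene_lexicon, load_medic_doid_map
from gexmine.syntax.lextag import tag, tokenize


def toks(s):
    return tag(tokenize(s))


class TestMirnas:
    @pytest.mark.parametrize(
        "surface,norm,arm",
        [
            ("MicroRNA-224", "mir-224", None),
            ("miR-1", "mir-1", None),
            ("microRNA1", "mir-1", None),
            ("miRNA-1", "mir-1", None),
            ("hsa-miR-1-3p", "mir-1", "3p"),
            ("miR-1a", "mir-1a", None),
            ("miR-1-5p", "mir-1", "5p"),
            ("let-7a", "let-7a", None),
        ],
    )
    def test_norms(self, surface, norm, arm):
        assert mirna_norm(surface) == (norm, arm)

    @pytest.mark.parametrize("variant", ["MIR-21", "miR-21", "microRNA-21", "MiRNA-21"])
    def test_case_insensitive_and_idempotent(self, variant):
        n1 = mirna_norm(variant)
        assert n1 == ("mir-21", None)
        assert mirna_norm(n1[0]) == n1  # normalizing a norm is a no-op

    def test_coordination_expansion(self):
        ms = tag_mirnas(0, toks("the expression of miR-143 and -195 in cancer tissues"))
        assert [m.norm_id for m in ms] == ["mir-143", "mir-195"]

    def test_not_a_mirna(self):
        assert mirna_norm("HER-2") is None
        assert tag_mirnas(0, toks("The mixture was stirred.")) == []


class TestGenes:
    def test_shp2_normalized(self):
        lx = load_gene_lexicon()
        ms = tag_genes(0, toks("Expression of Shp2 protein was significantly upregulated."), lx)
        assert len(ms) == 1 and ms[0].norm_id == "5781" and ms[0].surface == "Shp2"

    def test_no_hits(self):
        lx = NameLexicon({"gpc5": "2262"})
        assert tag_genes(0, toks("Nothing relevant here."), lx) == []

    def test_token_boundary(self):
        lx = NameLexicon({"gpc5": "2262"})
        ms = tag_genes(0, toks("The expression of the GPC5 gene was measured."), lx)
        assert len(ms) == 1 and ms[0].surface == "GPC5"

    def test_mirna_wins_overlap(self):
        # a lexicon entry that collides with a miRNA surface must lose
        lx = NameLexicon({"mir-21": "99999"})
        tk = toks("miR-21 was upregulated.")
        mirs = tag_mirnas(0, tk)
        assert tag_genes(0, tk, lx, mirs) == []


class TestDiseases:
    def test_long_form_and_abbreviation(self):
        lx = load_disease_lexicon()
        sentences = [toks("Oral Squamous Cell Carcinoma (OSCC) tissues were collected."),
                     toks("OSCC patients were compared with controls.")]
        abbrevs = find_abbreviations(sentences, lx)
        assert abbrevs.get("OSCC") == "DOID:0050866"
        ms0 = tag_diseases(0, sentences[0], lx, abbrevs)
        assert any(m.surface == "Oral Squamous Cell Carcinoma" and m.norm_id == "DOID:0050866" for m in ms0)
        ms1 = tag_diseases(1, sentences[1], lx, abbrevs)
        assert any(m.surface == "OSCC" and m.norm_id == "DOID:0050866" for m in ms1)

    def test_plural_surface_hits_singular_entry(self):
        lx = load_disease_lexicon()
        ms = tag_diseases(0, toks("pancreatic cancer tissues and ovarian cancers"), lx)
        assert {m.norm_id for m in ms} == {"DOID:1793", "DOID:2394"}

    def test_generic_word_not_a_disease_mention(self):
        lx = load_disease_lexicon()
        assert tag_diseases(0, toks("The tumor was large."), lx) == []

    def test_overlap_invariant(self):
        lx = load_disease_lexicon()
        tk = toks("non-small cell lung carcinoma and lung cancer tissues")
        ms = dedupe_overlaps(tag_diseases(0, tk, lx))
        spans = sorted((m.tok_start, m.tok_end) for m in ms)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestPhraseTyping:
    @pytest.mark.parametrize(
        "sentence,head,expected",
        [
            ("The expression of GPC5 gene was lower in lung cancer tissues.", "expression", True),
            ("miR-95 levels were increased in specimens.", "levels", True),
            ("OSCC tissues were examined.", "tissues", False),
        ],
    )
    def test_expression_phrase(self, parse, triggers, sentence, head, expected):
        g = parse(sentence)
        idx = next(n.index for n in g.nodes if n.surface == head)
        lx = load_gene_lexicon()
        tk = tag(tokenize(sentence))
        mentions = tag_genes(0, tk, lx, tag_mirnas(0, tk))
        assert type_expression_phrase(g, idx, mentions, triggers) is expected

    def test_mirna_head_is_expression_phrase(self, parse, triggers):
        s = "Plasma miR-187 was higher in OSCC patients than in normal individuals."
        g = parse(s)
        idx = next(n.index for n in g.nodes if n.surface == "miR-187")
        mentions = tag_mirnas(0, tag(tokenize(s)))
        assert type_expression_phrase(g, idx, mentions, triggers)

    @pytest.mark.parametrize(
        "sentence,head,expected",
        [
            ("Levels were higher in OSCC patients than in controls.", "patients", True),
            ("Levels were lower in normal ovaries than in tumors.", "ovaries", True),
            ("The glycan microarray was used.", "microarray", False),
        ],
    )
    def test_disease_sample(self, parse, triggers, sentence, head, expected):
        g = parse(sentence)
        idx = next(n.index for n in g.nodes if n.surface == head)
        assert type_disease_sample(g, idx, [], triggers) is expected

    def test_anaphoric_that_with_sample_complement(self, parse, triggers):
        g = parse("Expression was higher in tumors than that in normal tissues.")
        idx = next(n.index for n in g.nodes if n.surface == "that")
        assert type_disease_sample(g, idx, [], triggers)


class TestSerialization:
    @given(
        st.sampled_from(["GENE", "MIRNA", "DISEASE"]),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=1, max_value=5),
    )
    @settings(derandomize=True, max_examples=30)
    def test_mention_round_trips(self, etype, start, width):
        norm = {"GENE": "5781", "MIRNA": "mir-21", "DISEASE": "DOID:162"}[etype]
        m = EntityMention(0, start, start + width, 0, 4, "text", etype, norm)
        assert EntityMention.from_dict(m.to_dict()) == m


class TestPubTator:
    def test_reader_maps_medic_to_doid(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text(
            "7\t0\t4\tShp2\tGene\t5781\n"
            "7\t20\t33\tstomach cancer\tDisease\tMESH:D013274\n"
            "7\t40\t45\tweird\tDisease\tMESH:D999999\n"
        )
        anns = read_pubtator_annotations(p, load_medic_doid_map())
        assert anns["7"][0]["etype"] == "GENE" and anns["7"][0]["norm_id"] == "5781"
        assert anns["7"][1]["norm_id"] == "DOID:10534"
        assert anns["7"][2]["norm_id"] is None  # unmapped MEDIC id kept, no norm

    def test_malformed_line_raises(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("7\t0\t4\tShp2\n")
        with pytest.raises(ValueError):
            read_pubtator_annotations(p)
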