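"""Record assembly: type filtering, disease inference, frames, end-to-end."""

import pytest

from gexmine import assemble, build_abstract
from gexmine.assembly import (
    Pipeline,
    analyzed_sentence,
    infer_disease_from_context,
    investigation_sentence,
    normalize_level,
)


class TestWorkedExample:
    """The canonical single-sentence abstract: Shp2 upregulated in OSCC
    tissues vs normal tissues."""

    SENTENCE = (
        "Expression of Shp2 protein was significantly upregulated in "
        "Oral Squamous Cell Carcinoma (OSCC) tissues compared with the normal tissues."
    )

    def test_full_record(self):
        a = build_abstract("24439919", "Shp2 in oral cancer.", self.SENTENCE)
        recs = assemble(a)
        assert len(recs) == 1
        r = recs[0]
        assert r.relation_type == "A"
        assert r.entity_kind == "gene" and r.gene_id == "5781"
        assert r.level == "High"
        assert r.doid == "DOID:0050866"
        assert r.disease_sample == "OSCC tissues"
        assert r.compared_sample == "normal tissues"
        assert r.frame_of_reference == "Control"
        assert r.disease_source == "sentence"


class TestTypeFilter:
    def test_non_expression_aspect_rejected(self, pipeline):
        # a comparison about overall survival is not an expression statement
        a = build_abstract("1", "T.", "OS was significantly longer in arm A than in arm B.")
        assert pipeline.assemble(a) == []

    def test_consequence_statement_yields_nothing(self):
        a = build_abstract(
            "25762620", "C1GALT1 in breast cancer.",
            "Over-expression of C1GALT1 enhanced breast cancer cell growth, migration and invasion.",
        )
        assert assemble(a) == []

    def test_missing_expressed_entity_dropped(self, pipeline):
        a = build_abstract("1", "T.", "The expression levels were higher in tumor tissues than in normal tissues.")
        assert pipeline.assemble(a) == []
        assert any(r.code == "no-expressed-entity" for r in pipeline.reasons)


class TestLevels:
    @pytest.mark.parametrize(
        "lemma,expected",
        [("upregulate", "High"), ("lower", "Low"), ("decrease", "Low"), ("higher", "High"), ("high", "High"), ("low", "Low")],
    )
    def test_normalize_level(self, triggers, lemma, expected):
        assert normalize_level(lemma, triggers) == expected

    def test_unknown_lemma_is_none(self, triggers):
        assert normalize_level("purple", triggers) is None


class TestFrames:
    CASES = [
        (
            "Higher TP expression was observed in ovarian cancers than in normal ovaries.",
            "Control",
        ),
        (
            "The expression of PDECGF in T1 bladder carcinoma was twofold higher than that in Ta carcinomas.",
            "Not_Control",
        ),
        (
            "Expression of GCS was high in estrogen receptor (ER)-positive and HER-2 negative samples.",
            "none",
        ),
        (
            "MicroRNA-224 is frequently over-expressed in colorectal cancers.",
            "Control_Implicit",
        ),
    ]

    @pytest.mark.parametrize("sentence,frame", CASES)
    def test_frame(self, sentence, frame):
        a = build_abstract("1", "A study.", sentence)
        recs = assemble(a)
        assert len(recs) == 1
        assert recs[0].frame_of_reference == frame

    def test_control_ce_becomes_compared_sample(self):
        a = build_abstract(
            "1", "A study.", "Higher TP expression was observed in ovarian cancers than in normal ovaries."
        )
        r = assemble(a)[0]
        assert "normal" in r.compared_sample
        assert r.disease_sample == "ovarian cancers"
        assert r.doid == "DOID:2394"


class TestDiseaseInference:
    def test_title_source(self):
        a = build_abstract(
            "24649051", "Expression of microRNAs in gastric cancer.",
            "Conversely, the expression of miR-143 and -195 in cancer tissues was "
            "significantly lower compared to that in normal tissues.",
        )
        recs = assemble(a)
        assert {r.mirna_norm for r in recs} == {"mir-143", "mir-195"}
        assert all(r.doid == "DOID:10534" and r.disease_source == "title" for r in recs)

    def test_analyzed_source(self):
        a = build_abstract(
            "X2", "Serum profiling in surgical patients.",
            "Biomarker discovery remains an important goal. "
            "METHODS: A total of 140 patients with colorectal cancer were enrolled. "
            "miR-21 expression was significantly higher in cancer tissues than in adjacent normal tissues.",
        )
        recs = assemble(a)
        assert len(recs) == 1
        assert recs[0].doid == "DOID:9256" and recs[0].disease_source == "analyzed"

    def test_investigation_source(self):
        a = build_abstract(
            "X3", "Molecular characterization of urinary biomarkers.",
            "Markers were recorded at baseline. "
            "So the authors investigated the expression of TP in bladder cancer. "
            "TP expression was markedly higher in tumor tissues than in normal tissues.",
        )
        recs = assemble(a)
        assert len(recs) == 1
        assert recs[0].doid == "DOID:11054" and recs[0].disease_source == "investigation"

    def test_no_qualifying_location_leaves_disease_absent(self):
        # the only disease mention sits in a middle sentence with no
        # investigation/setup trigger: inference must NOT pick it up
        a = build_abstract(
            "X5", "A molecular study of tissue samples.",
            "Samples were stored at low temperature. "
            "Some patients had gastric cancer diagnosed elsewhere with no relevant follow-up. "
            "Subsequently further work followed. "
            "miR-21 expression was high in tumor tissues. "
            "Standard statistical procedures were applied. "
            "No definitive interpretation was offered.",
        )
        recs = [r for r in assemble(a) if r.mirna_norm == "mir-21"]
        assert len(recs) == 1
        assert recs[0].doid is None and recs[0].disease_source is None

    def test_investigation_trigger_needs_agent_or_passive(self, triggers):
        # "compared" as an entity separator must not qualify the sentence
        es_use = build_abstract(
            "1", "T.", "miR-21 expression was higher in tumor tissues compared with normal tissues."
        )
        assert not investigation_sentence(es_use.sentences[1], triggers)
        agent = build_abstract("1", "T.", "We investigated several options.")
        assert investigation_sentence(agent.sentences[1], triggers)
        purpose = build_abstract("1", "T.", "The purpose of this study was to investigate markers.")
        assert investigation_sentence(purpose.sentences[1], triggers)
        passive = build_abstract("1", "T.", "The associations were investigated in detail.")
        assert investigation_sentence(passive.sentences[1], triggers)

    def test_analyzed_needs_passive_and_number(self, triggers):
        yes = build_abstract("1", "T.", "A total of 140 patients were enrolled.")
        no_num = build_abstract("1", "T.", "Patients were enrolled.")
        active = build_abstract("1", "T.", "We enrolled 140 patients.")
        assert analyzed_sentence(yes.sentences[1], triggers)
        assert not analyzed_sentence(no_num.sentences[1], triggers)
        assert not analyzed_sentence(active.sentences[1], triggers)


class TestInvariants:
    def test_every_record_has_level_and_consistent_frame(self, pipeline):
        from gexmine.fixtures import generate_fixtures

        abstracts, _ = generate_fixtures(80, 17)
        records = pipeline.run(abstracts)
        assert records
        for r in records:
            assert r.level in ("High", "Low")
            if r.frame_of_reference == "Control_Implicit":
                assert r.relation_type == "B"
            if r.frame_of_reference == "Control" and r.relation_type == "A":
                assert any(
                    w in r.compared_sample.lower()
                    for w in ("control", "normal", "healthy", "adjacent")
                )
            assert (r.gene_id is None) != (r.mirna_norm is None)
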