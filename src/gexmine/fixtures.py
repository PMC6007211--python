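"""Synthetic abstract generator with gold annotations.

Generates small, fully annotated abstracts whose relation-bearing sentences
instantiate the comparison construction families the extractor covers
(P1–P5 for comparative statements, Q1–Q3 for plain-level statements), plus
consequence statements (``TypeC``, which must yield nothing) and trigger-free
distractors. A fraction of the comparative/implicit abstracts state only a
generic sample phrase ("cancer tissues") in the relation sentence and carry
the disease in the title or in a METHODS sentence with a patient count, so
the disease-context inference path is exercised end to end.

Generation is deterministic in the seed; the same (n, seed) always produces
byte-identical abstracts and gold records. Slot fillers come from the bundled
gene/disease lexicons, so the gold normalizations are recoverable offline.

What these fixtures emulate — and what they do not: sentences are
well-formed, single-relation, single-clause statements of the kinds the
pattern inventory covers. Real abstracts add cross-clause comparisons,
anaphora, unseen trigger variants and parser noise; exact recovery here
demonstrates internal consistency of the pipeline, not recall on arbitrary
prose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from random import Random

from .corpus import Abstract, build_abstract
from .records import ExpressionRecord

FAMILIES = ("P1", "P2", "P3", "P4", "P5", "Q1", "Q1P", "Q2", "Q3", "TypeC", "distractor")

DEFAULT_MIX: dict[str, float] = {
    "P1": 0.12,
    "P2": 0.10,
    "P3": 0.10,
    "P4": 0.08,
    "P5": 0.08,
    "Q1": 0.12,
    "Q1P": 0.08,
    "Q2": 0.08,
    "Q3": 0.08,
    "TypeC": 0.08,
    "distractor": 0.08,
}

GENES = [
    ("EGFR", "1956"), ("PTEN", "5728"), ("TP53", "7157"), ("KRAS", "3845"),
    ("STAT3", "6774"), ("MMP9", "4318"), ("BCL2", "596"), ("GALNT2", "2590"),
    ("FUT8", "2530"), ("MGAT5", "4249"), ("TIMP1", "7076"), ("NAMPT", "10135"),
]
MIRNAS = [
    ("miR-21", "mir-21"), ("miR-155", "mir-155"), ("miR-143", "mir-143"),
    ("miR-210", "mir-210"), ("miR-181a", "mir-181a"), ("miR-373", "mir-373"),
    ("let-7a", "let-7a"), ("miR-95", "mir-95"),
]
DISEASES = [
    ("gastric cancer", "DOID:10534"), ("colorectal cancer", "DOID:9256"),
    ("pancreatic cancer", "DOID:1793"), ("ovarian cancer", "DOID:2394"),
    ("breast cancer", "DOID:1612"), ("lung cancer", "DOID:1324"),
    ("prostate cancer", "DOID:10283"), ("hepatocellular carcinoma", "DOID:684"),
    ("melanoma", "DOID:1909"), ("bladder cancer", "DOID:11054"),
]

#: trigger-free, disease-free filler sentences
FILLERS = [
    "Samples were processed according to standard protocols.",
    "Statistical significance was defined as P < 0.05.",
    "The median age of participants was 58 years.",
    "Written informed consent was provided by all participants.",
    "Follow-up information was available for most cases.",
    "All experiments were performed in triplicate.",
]

NEUTRAL_TITLES = [
    "Expression profiling of serum biomarkers in clinical samples.",
    "A quantitative PCR study of candidate biomarkers.",
    "Molecular characterization of tissue specimens.",
]


@dataclass(frozen=True)
class FixtureSpec:
    """One synthetic abstract: family, slot fillers and derived RNG seed."""

    family: str
    seed: int
    pmid: str
    entity_surface: str
    entity_kind: str  # "gene" | "mirna"
    entity_norm: str
    disease: str
    doid: str
    context: str | None = None  # None | "title" | "methods"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown template family {self.family!r}")


@dataclass
class _Built:
    title: str
    body_sentences: list[str]
    #: (sentence text, record fields) for gold; index resolved later
    gold: list[dict] = field(default_factory=list)


def _weighted_choice(rng: Random, mix: dict[str, float]) -> str:
    total = sum(mix.values())
    x = rng.random() * total
    acc = 0.0
    for fam, w in mix.items():
        acc += w
        if x <= acc:
            return fam
    return next(reversed(mix))


def _make_spec(i: int, seed: int, mix: dict[str, float]) -> FixtureSpec:
    sub = (seed * 1_000_003 + i) % (2**31)
    rng = Random(sub)
    family = _weighted_choice(rng, mix)
    if rng.random() < 0.5:
        surface, norm = rng.choice(MIRNAS)
        kind = "mirna"
    else:
        surface, norm = rng.choice(GENES)
        kind = "gene"
    disease, doid = rng.choice(DISEASES)
    context = None
    if family in ("P1", "Q1") and rng.random() < 0.3:
        context = rng.choice(["title", "methods"])
    return FixtureSpec(
        family=family, seed=sub, pmid=f"SYN{i:05d}", entity_surface=surface,
        entity_kind=kind, entity_norm=norm, disease=disease, doid=doid, context=context,
    )


def _gold(spec: FixtureSpec, rel_type: str, level: str, frame: str, source: str,
          sample: str, compared: str | None, sentence: str,
          entity: tuple[str, str, str] | None = None) -> dict:
    surface, kind, norm = entity if entity else (spec.entity_surface, spec.entity_kind, spec.entity_norm)
    return dict(
        sentence=sentence,
        record=dict(
            pmid=spec.pmid,
            relation_type=rel_type,
            entity_text=surface,
            entity_kind=kind,
            gene_id=norm if kind == "gene" else None,
            mirna_norm=norm if kind == "mirna" else None,
            level=level,
            disease_text=None,  # filled from disease below when explicit
            doid=spec.doid,
            disease_sample=sample,
            compared_sample=compared,
            frame_of_reference=frame,
            disease_source=source,
        ),
    )


def _build(spec: FixtureSpec) -> _Built:
    rng = Random(spec.seed + 7)
    e, d = spec.entity_surface, spec.disease
    fam = spec.family
    high = rng.random() < 0.5
    built = _Built(title=f"Expression and clinical significance of {e} in {d}.", body_sentences=[])

    def emit(sentence: str, level: str, rel: str, frame: str, source: str,
             sample: str, compared: str | None, entity=None) -> None:
        built.body_sentences.append(sentence)
        built.gold.append(_gold(spec, rel, level, frame, source, sample, compared, sentence, entity))

    if fam == "P1" and spec.context is None:
        si, level = ("higher", "High") if high else ("lower", "Low")
        s = f"{e} expression was significantly {si} in {d} tissues than in normal tissues."
        emit(s, level, "A", "Control", "sentence", f"{d} tissues", "normal tissues")
    elif fam == "P1" and spec.context is not None:
        si, level = ("higher", "High") if high else ("lower", "Low")
        s = f"{e} expression was significantly {si} in cancer tissues than in adjacent normal tissues."
        emit(s, level, "A", "Control", "analyzed" if spec.context == "methods" else "title",
             "cancer tissues", "adjacent normal tissues")
    elif fam == "P2":
        si, level = ("increased", "High") if high else ("decreased", "Low")
        s = f"{e} levels were {si} in {d} tissues compared with adjacent normal tissues."
        emit(s, level, "A", "Control", "sentence", f"{d} tissues", "adjacent normal tissues")
    elif fam == "P3":
        si, level = ("Higher", "High") if high else ("Lower", "Low")
        verb = rng.choice(["found", "observed", "detected"])
        s = f"{si} {e} expression was {verb} in {d} tissues compared to normal tissues."
        emit(s, level, "A", "Control", "sentence", f"{d} tissues", "normal tissues")
    elif fam == "P4":
        si, level = ("increased", "High") if high else ("decreased", "Low")
        s = f"In comparison to normal tissues, {e} expression was significantly {si} in {d} tissues."
        emit(s, level, "A", "Control", "sentence", f"{d} tissues", "normal tissues")
    elif fam == "P5":
        si, level = ("higher", "High") if high else ("lower", "Low")
        verb = rng.choice(["presented", "showed", "exhibited"])
        s = f"Compared to controls, patients with {d} {verb} a {si} expression level of {e}."
        emit(s, level, "A", "Control", "sentence", f"patients with {d}", "controls")
    elif fam == "Q1" and spec.context is None:
        li, level = ("over-expressed", "High") if high else ("down-regulated", "Low")
        s = f"{e} is frequently {li} in {d}."
        emit(s, level, "B", "Control_Implicit", "sentence", d, None)
    elif fam == "Q1" and spec.context is not None:
        li, level = ("up-regulated", "High") if high else ("under-expressed", "Low")
        s = f"{e} was markedly {li} in tumor tissues."
        emit(s, level, "B", "Control_Implicit",
             "analyzed" if spec.context == "methods" else "title", "tumor tissues", None)
    elif fam == "Q1P":
        li, level = ("high", "High") if high else ("low", "Low")
        s = f"{e} expression was {li} in {d} tissues."
        emit(s, level, "B", "none", "sentence", f"{d} tissues", None)
    elif fam == "Q2":
        li, level = ("High", "High") if high else ("Low", "Low")
        verb = rng.choice(["detected", "found", "observed"])
        s = f"{li} {e} expression levels were {verb} in {d} tissues."
        emit(s, level, "B", "none", "sentence", f"{d} tissues", None)
    elif fam == "Q3":
        li, level = ("high", "High") if high else ("low", "Low")
        verb = rng.choice(["found", "detected", "observed"])
        s = f"We {verb} {li} expression levels of {e} in {d} cells."
        emit(s, level, "B", "none", "sentence", f"{d} cells", None)
    elif fam == "TypeC":
        variant = rng.choice([
            f"Over-expression of {e} enhanced {d} cell growth and invasion.",
            f"High {e} expression was associated with poor survival in {d} patients.",
        ])
        built.body_sentences.append(variant)
    elif fam == "distractor":
        built.body_sentences.append(rng.choice(FILLERS))

    # context carriers and neutral titles for inference cases
    if spec.context == "title":
        built.title = f"Expression of {e} in {d}."
        built.body_sentences.insert(0, rng.choice(FILLERS))
    elif spec.context == "methods":
        built.title = rng.choice(NEUTRAL_TITLES)
        count = rng.randrange(40, 300)
        built.body_sentences.insert(0, rng.choice(FILLERS))
        built.body_sentences.insert(
            1, f"METHODS: A total of {count} patients with {d} were enrolled."
        )
    else:
        # pad with fillers so relation sentences sit at varying indices
        fillers = rng.sample(FILLERS, k=rng.randrange(1, 4))
        for pos, f in enumerate(fillers):
            built.body_sentences.insert(rng.randrange(0, len(built.body_sentences) + 1), f)
    return built


def generate_fixtures(
    n: int, seed: int, mix: dict[str, float] | None = None
) -> tuple[list[Abstract], list[ExpressionRecord]]:
    """Generate ``n`` synthetic abstracts plus gold records (deterministic)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    mix = dict(mix or DEFAULT_MIX)
    unknown = set(mix) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families in mix: {sorted(unknown)}")
    abstracts: list[Abstract] = []
    gold: list[ExpressionRecord] = []
    for i in range(n):
        spec = _make_spec(i, seed, mix)
        built = _build(spec)
        abstract = build_abstract(spec.pmid, built.title, " ".join(built.body_sentences))
        abstracts.append(abstract)
        sentence_texts = [s.text for s in abstract.sentences]
        for g in built.gold:
            idx = sentence_texts.index(g["sentence"])
            rec = g["record"]
            disease_text = spec.disease if rec["disease_source"] == "sentence" else None
            gold.append(
                ExpressionRecord(
                    sentence_index=idx,
                    sentence_text=g["sentence"],
                    disease_text=disease_text if disease_text else rec["disease_text"],
                    **{k: v for k, v in rec.items() if k != "disease_text"},
                )
            )
    gold.sort(key=lambda r: (r.pmid, r.sentence_index, r.entity_text))
    return abstracts, gold


def abstracts_to_tsv_lines(abstracts: list[Abstract]) -> list[str]:
    return [f"{a.pmid}\t{a.title}\t{a.body}" for a in abstracts]
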