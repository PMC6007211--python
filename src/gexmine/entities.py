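"""Entity detection and phrase typing.

Detects gene, microRNA and disease mentions in tokenized sentences and types
noun phrases as *expression* phrases or *disease samples*. Genes and diseases
come from bundled lexicon taggers (longest match over lemmas,
case-insensitive); microRNAs from a regular-expression family following the
miRBase naming convention (species prefix, stem, number, letter suffix, arm
suffix, e.g. ``hsa-miR-1-3p``). A reader for precomputed annotation files in
the PubTator offset format is provided as an alternative tagger for users who
have such files; genes and proteins are deliberately not distinguished.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

from .lexicon import NameLexicon, TriggerLexicons
from .syntax.graph import DepGraph
from .syntax.lextag import Token

ETYPES = ("GENE", "MIRNA", "DISEASE", "EXPRESSION", "DISEASE_SAMPLE")


@dataclass(frozen=True)
class EntityMention:
    sentence_index: int
    tok_start: int  # token span, half-open
    tok_end: int
    start: int  # character span within the sentence, half-open
    end: int
    surface: str
    etype: str
    norm_id: str | None = None
    arm: str | None = None  # miRNA arm suffix (3p/5p), kept separately

    def __post_init__(self) -> None:
        if self.etype not in ETYPES:
            raise ValueError(f"bad etype {self.etype!r}")
        if self.etype == "DISEASE" and self.norm_id is not None and not re.fullmatch(
            r"DOID:\d+", self.norm_id
        ):
            raise ValueError(f"disease norm must look like DOID:<n>, got {self.norm_id!r}")

    def covers_token(self, i: int) -> bool:
        return self.tok_start <= i < self.tok_end

    def within(self, span: tuple[int, int]) -> bool:
        return span[0] <= self.tok_start and self.tok_end <= span[1]

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EntityMention":
        return cls(**d)


# ------------------------------------------------------------------ miRNAs

_MIRNA_TOKEN_RE = re.compile(
    r"^(?P<species>[a-z]{3,4}-)?(?P<stem>mir|mirna|microrna|let)"
    r"(?P<sep>[- ]?)(?P<num>\d+)(?P<letter>[a-z]?)(?P<variant>-\d+)?(?P<arm>-[35]p)?$",
    re.IGNORECASE,
)
_ELIDED_RE = re.compile(r"^-?(?P<num>\d+)(?P<letter>[a-z]?)(?P<arm>-[35]p)?$")


def mirna_norm(surface: str) -> tuple[str, str | None] | None:
    """Canonical (norm, arm) for a miRNA surface form, or None if not one."""
    m = _MIRNA_TOKEN_RE.match(surface.strip())
    if not m:
        return None
    stem = "let" if m.group("stem").lower() == "let" else "mir"
    norm = f"{stem}-{m.group('num')}{m.group('letter').lower()}"
    if m.group("variant"):
        norm += m.group("variant")
    arm = m.group("arm")[1:] if m.group("arm") else None
    return norm, arm


def tag_mirnas(sentence_index: int, tokens: list[Token]) -> list[EntityMention]:
    """microRNA mentions, including elided coordinated stems ("miR-143 and -195")."""
    out: list[EntityMention] = []
    last_mirna_stem: str | None = None
    for i, t in enumerate(tokens):
        res = mirna_norm(t.surface)
        if res is not None:
            norm, arm = res
            out.append(
                EntityMention(sentence_index, i, i + 1, t.start, t.end, t.surface, "MIRNA", norm, arm)
            )
            last_mirna_stem = norm.split("-")[0]
            continue
        # bare "-195" coordinated with a preceding full miRNA mention
        if last_mirna_stem is not None and i >= 1 and tokens[i - 1].pos == "CC":
            m = _ELIDED_RE.match(t.surface)
            if m and any(ch.isdigit() for ch in t.surface):
                norm = f"{last_mirna_stem}-{m.group('num')}{m.group('letter').lower()}"
                arm = m.group("arm")[1:] if m.group("arm") else None
                out.append(
                    EntityMention(sentence_index, i, i + 1, t.start, t.end, t.surface, "MIRNA", norm, arm)
                )
    return out


# ---------------------------------------------------------------- lexicons

def _ngram_tag(
    sentence_index: int,
    tokens: list[Token],
    lexicon: NameLexicon,
    etype: str,
    blocked: set[int],
    norm_map=None,
) -> list[EntityMention]:
    """Greedy left-to-right longest-match over lemma n-grams."""
    out: list[EntityMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i in blocked:
            i += 1
            continue
        hit = None
        for width in range(min(lexicon.max_len, n - i), 0, -1):
            if any(j in blocked for j in range(i, i + width)):
                continue
            lemmas = tuple(tokens[j].lemma for j in range(i, i + width))
            ident = lexicon.get(lemmas)
            if ident is None:
                surfaces = tuple(tokens[j].surface for j in range(i, i + width))
                ident = lexicon.get(surfaces)
            if ident is not None:
                hit = (width, ident)
                break
        if hit is None:
            i += 1
            continue
        width, ident = hit
        if norm_map is not None:
            ident = norm_map(ident)
        out.append(
            EntityMention(
                sentence_index,
                i,
                i + width,
                tokens[i].start,
                tokens[i + width - 1].end,
                " ".join(t.surface for t in tokens[i : i + width]),
                etype,
                ident,
            )
        )
        i += width
    return out


def tag_genes(
    sentence_index: int,
    tokens: list[Token],
    lexicon: NameLexicon,
    mirna_mentions: list[EntityMention] | None = None,
) -> list[EntityMention]:
    """GENE mentions; on overlap the more specific miRNA pattern wins."""
    blocked = set()
    for m in mirna_mentions or []:
        blocked.update(range(m.tok_start, m.tok_end))
    return _ngram_tag(sentence_index, tokens, lexicon, "GENE", blocked)


def tag_diseases(
    sentence_index: int,
    tokens: list[Token],
    lexicon: NameLexicon,
    abbreviations: dict[str, str] | None = None,
) -> list[EntityMention]:
    """DISEASE mentions with DOID norms; in-abstract abbreviations resolve to
    the DOID of their parenthetically defined long form."""
    out = _ngram_tag(sentence_index, tokens, lexicon, "DISEASE", set())
    covered = set()
    for m in out:
        covered.update(range(m.tok_start, m.tok_end))
    for i, t in enumerate(tokens):
        if i in covered or not abbreviations:
            continue
        doid = abbreviations.get(t.surface)
        if doid is not None:
            out.append(
                EntityMention(sentence_index, i, i + 1, t.start, t.end, t.surface, "DISEASE", doid)
            )
    return sorted(out, key=lambda m: m.tok_start)


# -------------------------------------------------- abbreviation linking

_SHORT_RE = re.compile(r"^[A-Za-z][A-Za-z0-9-]{1,9}$")


def find_abbreviations(
    sentences_tokens: list[list[Token]], disease_lexicon: NameLexicon
) -> dict[str, str]:
    """Long-form/short-form parenthetical pairs, per abstract.

    Returns short form -> DOID for short forms whose candidate long form
    (the tokens preceding the parenthesis, matched right-to-left against the
    short form's initial characters) resolves in the disease lexicon.
    """
    table: dict[str, str] = {}
    for tokens in sentences_tokens:
        for i, t in enumerate(tokens):
            if t.surface != "(" or i + 2 >= len(tokens) + 1:
                continue
            if i + 2 < len(tokens) and tokens[i + 2].surface == ")" and _SHORT_RE.match(
                tokens[i + 1].surface
            ):
                short = tokens[i + 1].surface
                window = tokens[max(0, i - 2 * len(short)) : i]
                if not window:
                    continue
                if _letters_match(short, [w.surface for w in window]):
                    # resolve the longest suffix of the window in the lexicon
                    for start in range(len(window)):
                        lemmas = tuple(w.lemma for w in window[start:])
                        doid = disease_lexicon.get(lemmas)
                        if doid is not None:
                            table[short] = doid
                            break
    return table


def _letters_match(short: str, words: list[str]) -> bool:
    """Schwartz–Hearst-style check: the short form's characters appear in
    order in the long form, the first one at the start of a word."""
    chars = [c.lower() for c in short if c.isalnum()]
    text = " ".join(words).lower()
    pos = len(text)
    for c in reversed(chars[1:]):
        pos = text.rfind(c, 0, pos)
        if pos < 0:
            return False
    first = text.rfind(" " + chars[0], 0, pos)
    return text.startswith(chars[0]) or first >= 0


# ------------------------------------------------------------ phrase typing

def type_expression_phrase(
    graph: DepGraph, np_head: int, mentions: list[EntityMention], lexicons: TriggerLexicons
) -> bool:
    """An NP is an *expression* phrase if its head noun is an expression
    trigger, or the head itself is a gene/miRNA mention."""
    head = graph.node(np_head)
    if head.lemma in lexicons.expression_nouns:
        return True
    return any(m.etype in ("GENE", "MIRNA") and m.covers_token(np_head) for m in mentions)


def type_disease_sample(
    graph: DepGraph, np_head: int, mentions: list[EntityMention], lexicons: TriggerLexicons
) -> bool:
    """An NP is a disease sample if it is a disease mention, its head is a
    disease-sample or generic disease word, or it is an anaphoric "that"
    standing for a sample phrase ("... than that in normal tissues")."""
    head = graph.node(np_head)
    if any(m.etype == "DISEASE" and m.covers_token(np_head) for m in mentions):
        return True
    if head.lemma in lexicons.disease_sample_heads or head.lemma in lexicons.generic_disease_phrases:
        return True
    if head.lemma in {"that", "those"}:
        return any(
            type_disease_sample(graph, e.dependent, mentions, lexicons)
            for e in graph.out_edges(np_head)
            if e.label == "nmod:in"
        )
    return False


# ------------------------------------------------------------- PubTator IO

def read_pubtator_annotations(
    path: str | Path, medic_doid: dict[str, str] | None = None
) -> dict[str, list[dict]]:
    """Read precomputed annotations in PubTator offset format:
    ``PMID<TAB>start<TAB>end<TAB>text<TAB>type<TAB>id``; offsets refer to the
    title + single space + abstract body concatenation. Disease identifiers in
    MEDIC vocabularies are mapped to DOIDs where the mapping table resolves;
    unmapped mentions are kept with no norm (callers may count them)."""
    out: dict[str, list[dict]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"line {lineno}: expected 6 tab-separated fields")
            pmid, start, end, text, etype_raw, ident = parts[:6]
            etype = {"gene": "GENE", "disease": "DISEASE", "mirna": "MIRNA"}.get(
                etype_raw.lower()
            )
            if etype is None:
                continue
            norm: str | None = ident or None
            if etype == "DISEASE" and norm is not None and not norm.startswith("DOID:"):
                norm = (medic_doid or {}).get(norm)
            out.setdefault(pmid, []).append(
                dict(start=int(start), end=int(end), surface=text, etype=etype, norm_id=norm)
            )
    return out


def project_annotations(
    raw: list[dict], sentence_offsets: list[tuple[int, int]], sentences_tokens: list[list[Token]]
) -> list[EntityMention]:
    """Project abstract-level offset annotations onto tokenized sentences."""
    out: list[EntityMention] = []
    for ann in raw:
        for s_idx, (s_lo, s_hi) in enumerate(sentence_offsets):
            if not (s_lo <= ann["start"] and ann["end"] <= s_hi):
                continue
            lo, hi = ann["start"] - s_lo, ann["end"] - s_lo
            toks = sentences_tokens[s_idx]
            t_idx = [i for i, t in enumerate(toks) if t.start < hi and t.end > lo]
            if not t_idx:
                continue
            out.append(
                EntityMention(
                    s_idx, t_idx[0], t_idx[-1] + 1, lo, hi, ann["surface"], ann["etype"], ann["norm_id"]
                )
            )
            break
    return out


def dedupe_overlaps(mentions: list[EntityMention]) -> list[EntityMention]:
    """Enforce the no-overlap invariant per etype (earliest, then longest wins)."""
    out: list[EntityMention] = []
    taken: dict[str, set[int]] = {}
    for m in sorted(mentions, key=lambda m: (m.tok_start, -(m.tok_end - m.tok_start))):
        used = taken.setdefault(m.etype, set())
        span = set(range(m.tok_start, m.tok_end))
        if span & used:
            continue
        used |= span
        out.append(m)
    return out
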