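"""Abstract collections: reading, sentence splitting, tokenization, prefilter.

Input formats: Medline/PubMed XML (``PubmedArticleSet``), tab-separated
``pmid<TAB>title<TAB>abstract``, and plain-text one-abstract-per-file
directories. The title is sentence index 0 and participates in extraction and
disease-context inference. Text is NFKC-normalized before tokenization, and
character offsets are 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .lexicon import TriggerLexicons
from .syntax.lextag import Token, tag, tokenize
from .util import nfkc

log = logging.getLogger("gexmine")

SECTION_HINTS = ("TITLE", "FIRST", "BODY", "METHODS", "CONCLUSION")

_LABEL_MAP = {
    "METHODS": "METHODS",
    "METHOD": "METHODS",
    "PATIENTS AND METHODS": "METHODS",
    "MATERIALS AND METHODS": "METHODS",
    "CONCLUSION": "CONCLUSION",
    "CONCLUSIONS": "CONCLUSION",
}


@dataclass
class Sentence:
    abstract_id: str
    index: int
    text: str
    tokens: list[Token]
    section_hint: str
    #: offset of this sentence in the title + " " + body concatenation
    abs_start: int = 0

    def __post_init__(self) -> None:
        if self.section_hint not in SECTION_HINTS:
            raise ValueError(f"bad section_hint {self.section_hint!r}")
        if (self.section_hint == "TITLE") != (self.index == 0):
            raise ValueError("TITLE hint must coincide with sentence index 0")


@dataclass
class Abstract:
    pmid: str
    title: str
    body: str
    sentences: list[Sentence] = field(default_factory=list)


# -------------------------------------------------------- sentence splitting

_NO_SPLIT_BEFORE = re.compile(
    r"\b(?:vs|al|fig|figs|e\.g|i\.e|ca|approx|no|resp|spp|etc)\.$", re.IGNORECASE
)
# a single capital + period is an initial ("S. aureus") only before lowercase
_INITIAL = re.compile(r"\b[A-Z]\.$")
_BOUNDARY = re.compile(r"[.!?]+(?=\s)")


def split_sentences(text: str) -> list[str]:
    """Split text into sentences, protecting common abbreviations.

    Joining the result on single spaces preserves every non-whitespace
    character of the input.
    """
    text = text.strip()
    if not text:
        return []
    out: list[str] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        prefix = text[start:end].strip()
        nxt = text[end:].lstrip()
        if not nxt:
            break
        if _NO_SPLIT_BEFORE.search(prefix):
            continue
        if _INITIAL.search(prefix) and nxt[0].islower():
            continue
        # sentences may open lowercase here ("miR-21 expression was ...")
        if not (nxt[0].isalnum() or nxt[0] in "\"'("):
            continue
        out.append(prefix)
        start = end
    tail = text[start:].strip()
    if tail:
        out.append(tail)
    return out


_SEGMENT_LABEL = re.compile(r"^([A-Z][A-Z /&]{2,40}):\s*")


def _body_segments(body: str) -> list[tuple[str | None, str]]:
    """Split a structured-abstract body into (label, text) segments."""
    matches = list(re.finditer(r"(?:^|(?<=[.!?]\s))([A-Z][A-Z /&]{2,40}):\s*", body))
    if not matches:
        return [(None, body)]
    segments: list[tuple[str | None, str]] = []
    if matches[0].start() > 0:
        segments.append((None, body[: matches[0].start()]))
    for i, m in enumerate(matches):
        end = matches[i + 1].start() if i + 1 < len(matches) else len(body)
        segments.append((m.group(1), body[m.start() : end]))
    return segments


def build_abstract(pmid: str, title: str, body: str) -> Abstract:
    """Tokenize and sentence-split one abstract; title is sentence 0."""
    title = nfkc(title).strip()
    body = nfkc(body).strip()
    abstract = Abstract(pmid=pmid, title=title, body=body)
    raw: list[tuple[str, str | None]] = [(title, None)]
    for label, seg_text in _body_segments(body):
        for s in split_sentences(seg_text):
            raw.append((s, label))
    n_body = len(raw) - 1
    offset = 0
    for idx, (text, label) in enumerate(raw):
        if idx == 0:
            hint = "TITLE"
        elif label is not None and label in _LABEL_MAP:
            hint = _LABEL_MAP[label]
        elif idx == 1:
            hint = "FIRST"
        elif idx >= len(raw) - 2 and n_body > 2:
            hint = "CONCLUSION"
        else:
            hint = "BODY"
        toks = tag(tokenize(text))
        abstract.sentences.append(
            Sentence(
                abstract_id=pmid,
                index=idx,
                text=text,
                tokens=toks,
                section_hint=hint,
                abs_start=offset,
            )
        )
        offset += len(text) + 1
    return abstract


# ------------------------------------------------------------------- readers

def read_medline_xml(path: str | Path) -> list[Abstract]:
    """Read a PubMed/Medline ``PubmedArticleSet`` XML file.

    Structured-abstract section labels are preserved into section hints.
    Articles without abstract text are skipped with a warning.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    out: list[Abstract] = []
    for art in tree.iter("PubmedArticle"):
        pmid_el = art.find(".//PMID")
        pmid = pmid_el.text.strip() if pmid_el is not None and pmid_el.text else "?"
        title_el = art.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        parts: list[str] = []
        for at in art.findall(".//Abstract/AbstractText"):
            text = "".join(at.itertext()).strip()
            if not text:
                continue
            label = at.get("Label") or at.get("NlmCategory")
            if label:
                parts.append(f"{label.upper()}: {text}")
            else:
                parts.append(text)
        body = " ".join(parts)
        if not body:
            log.warning("PMID %s: empty abstract, skipped", pmid)
            continue
        out.append(build_abstract(pmid, title, body))
    return out


def read_tsv(path: str | Path) -> list[Abstract]:
    """Read ``pmid<TAB>title<TAB>abstract`` lines; malformed lines are skipped."""
    out: list[Abstract] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                log.warning("line %d: expected 3 fields, got %d — skipped", lineno, len(parts))
                continue
            pmid, title, body = parts
            out.append(build_abstract(pmid.strip(), title, body))
    return out


def read_text_dir(path: str | Path) -> list[Abstract]:
    """One abstract per ``*.txt`` file: first line title, rest body; the file
    stem is used as the identifier."""
    out: list[Abstract] = []
    for p in sorted(Path(path).glob("*.txt")):
        text = p.read_text(encoding="utf-8")
        first, _, rest = text.partition("\n")
        out.append(build_abstract(p.stem, first.strip(), rest.strip()))
    return out


# ------------------------------------------------------------------ prefilter

def prefilter(sentence: Sentence, lexicons: TriggerLexicons) -> bool:
    """True iff the sentence contains at least one expression/comparison
    trigger lemma; sentences failing this are not parsed."""
    triggers = lexicons.prefilter_lemmas
    return any(t.lemma in triggers for t in sentence.tokens)
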