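"""Tokenization, part-of-speech tagging and lemmatization.

A compact deterministic tagger tuned to the declarative style of results
sentences in biomedical abstracts. Closed classes come from word lists, verb
inflections from an inflection table generated over the domain verb lexicon,
and everything else defaults to a noun reading — which is the right prior for
gene symbols, microRNA names and disease terms. Comparative adjectives keep
their own lemma ("higher" stays "higher", not "high"): the comparative form
is what signals an implied baseline, and collapsing it would destroy the
distinction between comparative and plain level indicators downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# ---------------------------------------------------------------- word lists

DETERMINERS = {"the", "a", "an", "this", "these", "those", "both", "all", "each", "either", "no", "such"}
PREPOSITIONS = {
    "in", "of", "with", "to", "from", "at", "by", "for", "on", "into", "between",
    "among", "during", "via", "within", "under", "across", "per", "against",
    "than", "versus", "vs", "vs.", "after", "before", "following", "as", "upon",
}
PRONOUNS = {"we", "they", "it", "i", "he", "she", "you"}
CONJUNCTIONS = {"and", "or", "but", "nor"}
COPULAS = {"is", "are", "was", "were", "be", "been", "being", "am"}
AUXILIARIES = {"have", "has", "had", "do", "does", "did"}
MODALS = {"can", "could", "may", "might", "will", "would", "shall", "should", "must"}

ADJECTIVES = {
    "high", "low", "normal", "adjacent", "healthy", "human", "murine", "primary",
    "metastatic", "cancerous", "noncancerous", "non-cancerous", "benign", "malignant",
    "right", "left", "invasive", "positive", "negative", "chronic", "acute", "old",
    "cancer-free", "frequency-matched", "nontumor", "non-tumor", "non-tumour",
    "abundant", "strong", "weak", "minimal", "absent", "significant", "different",
    "differential", "early", "late", "advanced", "severe", "mild", "total",
    "adrenocortical", "ovarian", "gastric", "pancreatic", "colorectal", "hepatic",
    "pulmonary", "renal", "cervical", "esophageal", "papillary", "follicular",
    "same", "most", "several", "many", "few", "various",
}
COMPARATIVES = {
    "higher", "lower", "greater", "larger", "smaller", "stronger", "weaker",
    "better", "worse", "richer", "older", "younger", "deeper", "broader",
}
ADVERB_EXTRA = {
    "not", "never", "often", "however", "thus", "so", "also", "further",
    "moreover", "too", "very", "twofold", "threefold", "especially", "most",
}

NUMBER_WORDS = {
    "one", "two", "three", "four", "five", "six", "seven", "eight", "nine", "ten",
    "eleven", "twelve", "thirteen", "fourteen", "fifteen", "sixteen", "seventeen",
    "eighteen", "nineteen", "twenty", "thirty", "forty", "fifty", "sixty",
    "seventy", "eighty", "ninety", "hundred",
}

#: base forms of every verb the pipeline ever needs to recognize
VERB_BASES = {
    "find", "observe", "detect", "note", "identify", "show", "present", "exhibit",
    "display", "demonstrate", "reveal", "indicate", "confirm", "report", "suggest",
    "express", "over-express", "overexpress", "under-express", "underexpress",
    "up-regulate", "upregulate", "down-regulate", "downregulate", "co-express",
    "increase", "decrease", "reduce", "elevate", "diminish", "decline", "raise",
    "amplify", "enhance", "inhibit", "promote", "suppress", "correlate", "associate",
    "investigate", "examine", "analyze", "analyse", "evaluate", "study", "compare",
    "test", "enroll", "enrol", "recruit", "collect", "measure", "explore", "assess",
    "obtain", "include", "use", "perform", "conduct", "establish", "derive",
    "modulate", "regulate", "mediate", "induce", "profile", "match", "treat",
    "base", "relate", "involve",
}

IRREGULAR_VERBS = {
    "found": ("find", "VBD"),
    "shown": ("show", "VBN"),
    "seen": ("see", "VBN"),
    "was": ("be", "VBD"),
    "were": ("be", "VBD"),
    "is": ("be", "VBZ"),
    "are": ("be", "VBP"),
    "been": ("be", "VBN"),
    "being": ("be", "VBG"),
    "am": ("be", "VBP"),
    "has": ("have", "VBZ"),
    "had": ("have", "VBD"),
    "did": ("do", "VBD"),
    "done": ("do", "VBN"),
}

IRREGULAR_NOUNS = {
    "men": "man", "women": "woman", "mice": "mouse", "children": "child",
    "analyses": "analysis", "diagnoses": "diagnosis", "prognoses": "prognosis",
    "metastases": "metastasis", "hypotheses": "hypothesis", "feet": "foot",
    "criteria": "criterion", "data": "data", "sera": "serum", "carcinomata": "carcinoma",
}

_MIRNA_RE = re.compile(
    r"^(?:[a-z]{3,4}-)?(?:mir|mirna|microrna|let)[- ]?\d+[a-z]?(?:-\d+)?(?:-[35]p)?$",
    re.IGNORECASE,
)


def _inflections() -> dict[str, tuple[str, str]]:
    """form -> (base, tag) table generated from VERB_BASES."""
    table: dict[str, tuple[str, str]] = {}
    doubling = {"enrol": "enroll"}  # enrol -> enrolled (British single-l base)
    for base in VERB_BASES:
        stem = base
        if base in doubling:
            past = doubling[base] + "ed"
            ger = doubling[base] + "ing"
        elif stem.endswith("e"):
            past = stem + "d"
            ger = stem[:-1] + "ing"
        elif stem.endswith("y") and len(stem) > 2 and stem[-2] not in "aeiou":
            past = stem[:-1] + "ied"
            ger = stem + "ing"
        else:
            past = stem + "ed"
            ger = stem + "ing"
        if stem.endswith(("s", "sh", "ch", "x", "z")):
            third = stem + "es"
        elif stem.endswith("y") and len(stem) > 2 and stem[-2] not in "aeiou":
            third = stem[:-1] + "ies"
        else:
            third = stem + "s"
        table[past] = (base, "VBD")  # VBD/VBN resolved in context
        table[third] = (base, "VBZ")
        table[ger] = (base, "VBG")
        table[base] = (base, "VB")
    return table


VERB_FORMS = _inflections()


def noun_lemma(word: str) -> str:
    w = word.lower()
    if w in IRREGULAR_NOUNS:
        return IRREGULAR_NOUNS[w]
    if _MIRNA_RE.match(w):
        return w
    if len(w) > 3 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 3 and w.endswith(("ses", "xes", "zes", "ches", "shes")):
        return w[:-2]
    if len(w) > 2 and w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


# ---------------------------------------------------------------- tokenizer

_ABBREVIATIONS = {"vs.", "et", "al.", "fig.", "figs.", "e.g.", "i.e.", "ca.", "approx.", "no.", "spp.", "resp."}

_TOKEN_RE = re.compile(r"\(|\)|\[|\]|[,;]|[^\s()\[\],;]+")


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str
    start: int
    end: int


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split into (surface, start, end) triples with 0-based half-open offsets."""
    raw: list[tuple[str, int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        raw.append((m.group(), m.start(), m.end()))
    out: list[tuple[str, int, int]] = []
    for surf, s, e in raw:
        # split a trailing colon (structured-abstract labels: "METHODS:")
        if len(surf) > 1 and surf.endswith(":"):
            out.append((surf[:-1], s, e - 1))
            out.append((":", e - 1, e))
            continue
        # split a trailing sentence period, keeping known abbreviations intact
        if len(surf) > 1 and surf.endswith(".") and surf.lower() not in _ABBREVIATIONS and not re.match(r"^\d+(\.\d+)*\.$", surf):
            out.append((surf[:-1], s, e - 1))
            out.append((".", e - 1, e))
            continue
        out.append((surf, s, e))
    return out


# ---------------------------------------------------------------- tagger

def _base_tag(surf: str) -> tuple[str, str]:
    """(lemma, pos) before context disambiguation."""
    w = surf.lower()
    if re.fullmatch(r"[.:;,()\[\]<>=%*/+-]", surf):
        return w, "PUNCT"
    if w in IRREGULAR_VERBS:
        base, tag = IRREGULAR_VERBS[w]
        return base, tag
    if w in DETERMINERS:
        return w, "DT"
    if w in PRONOUNS:
        return w, "PRP"
    if w in CONJUNCTIONS:
        return w, "CC"
    if w in MODALS:
        return w, "MD"
    if w == "to":
        return w, "TO"
    if w in PREPOSITIONS:
        return w, "IN"
    if w in COMPARATIVES:
        return w, "JJR"
    if re.fullmatch(r"\d+(?:[.,]\d+)*(?:-fold)?", w) or w in NUMBER_WORDS:
        return w, "CD"
    if w in VERB_FORMS:
        base, tag = VERB_FORMS[w]
        return base, tag
    if w in ADJECTIVES:
        return w, "JJ"
    if w.endswith("ly") and len(w) > 3 or w in ADVERB_EXTRA:
        return w, "RB"
    if w.startswith("-") and len(w) > 1:
        # hyphen-led fragment: modifier ("-positive") or elided miRNA ("-195")
        if re.fullmatch(r"-\d+[a-z]?(?:-[35]p)?", w):
            return w, "NN"
        return w, "JJ"
    if w.endswith(("ed", "en")) and len(w) > 4:
        return w, "VBD"  # unknown participle-ish form
    if _MIRNA_RE.match(w):
        return w, "NNP"
    if any(c.isupper() for c in surf[1:]) or any(c.isdigit() for c in surf):
        return w, "NNP"  # mixed case / digits: entity-like proper noun
    if w.endswith("s") and not w.endswith(("ss", "us", "is", "sis")) and len(w) > 3:
        return noun_lemma(w), "NNS"
    return noun_lemma(w), "NN"


def tag(tokens: list[tuple[str, int, int]]) -> list[Token]:
    """Tag a tokenized sentence, resolving VBD/VBN and noun/verb ambiguity."""
    base = [_base_tag(surf) for surf, _, _ in tokens]
    n = len(base)
    out: list[Token] = []
    for i, ((surf, s, e), (lemma, pos)) in enumerate(zip(tokens, base)):
        # participle after a copula/auxiliary (skipping adverbs) is VBN
        if pos in {"VBD", "VBN"}:
            j = i - 1
            while j >= 0 and base[j][1] == "RB":
                j -= 1
            if j >= 0 and (base[j][0] in {"be", "have"} or base[j][1] == "MD"):
                pos = "VBN"
            else:
                # prenominal participle ("Increased TP expression") acts as VBN modifier
                k = i + 1
                while k < n and base[k][1] in {"RB", "JJ", "JJR"}:
                    k += 1
                if k < n and base[k][1] in {"NN", "NNS", "NNP", "CD"} and (
                    i == 0 or base[i - 1][1] in {"DT", "IN", "CC", "PUNCT", "JJ"}
                ):
                    pos = "VBN"
        # sentence-initial "So"/"Thus" adverbial
        if i == 0 and lemma in {"so", "thus", "conversely", "however"}:
            pos = "RB"
        out.append(Token(surf, lemma, pos, s, e))
    return out
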