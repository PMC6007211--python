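"""Small shared helpers: unicode normalization, detokenization, truncation."""

from __future__ import annotations

import math
import unicodedata


def nfkc(text: str) -> str:
    """NFKC-normalize text (en-dashes, Greek letters, ligatures from Medline)."""
    return unicodedata.normalize("NFKC", text)


def detokenize(tokens: list[str]) -> str:
    """Join tokens back into readable text.

    Closing punctuation attaches left, opening parens attach right. This is a
    display operation only; offsets always refer to the original sentence.
    """
    out: list[str] = []
    for tok in tokens:
        if not out:
            out.append(tok)
        elif tok in {")", "]", ",", ";", ":", ".", "%", "?", "!"}:
            out[-1] += tok
        elif out[-1].endswith(("(", "[")):
            out[-1] += tok
        elif tok.startswith("-") and out and out[-1].endswith(")"):
            out[-1] += tok  # "(ER)" + "-positive"
        else:
            out.append(tok)
    return " ".join(out)


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals; used for precision/recall."""
    return math.floor(x * 100.0 + 1e-9) / 100.0


def round2(x: float) -> float:
    """Round half-up to two decimals; used for the F-score."""
    return math.floor(x * 100.0 + 0.5) / 100.0
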