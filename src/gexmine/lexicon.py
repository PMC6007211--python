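"""Trigger, gene and disease lexicons.

All matching in the pipeline is on lowercase lemmas. Trigger lists live in a
YAML file (one list per trigger class); gene and disease lexicons are TSV
``name<TAB>identifier`` tables. Bundled defaults ship under
``gexmine/data`` and every loader accepts a path override, so the whole
trigger inventory is user-editable without touching code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

_TRIGGER_KEYS = (
    "expression_nouns",
    "si_high",
    "si_low",
    "li_implicit_high",
    "li_implicit_low",
    "li_plain_high",
    "li_plain_low",
    "entity_separators",
    "entity_separators_extended",
    "disease_sample_heads",
    "generic_disease_phrases",
    "control_modifiers",
    "agent_words",
    "purpose_words",
    "investigation_triggers",
    "analyzed_triggers",
    "observation_verbs",
    "report_verbs",
)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gexmine").joinpath("data", name)))


@dataclass(frozen=True)
class TriggerLexicons:
    """Named sets of lowercase trigger lemmas (multi-word entries space-joined)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    #: include the opt-in temporal entity separators ("after", "following")
    extended_separators: bool = False

    def __post_init__(self) -> None:
        for key in _TRIGGER_KEYS:
            if key not in self.sets:
                raise ValueError(f"missing trigger list: {key}")
        if self.sets["si_high"] & self.sets["si_low"]:
            raise ValueError("si_high and si_low overlap")
        if (self.sets["li_implicit_high"] | self.sets["li_implicit_low"]) & (
            self.sets["li_plain_high"] | self.sets["li_plain_low"]
        ):
            raise ValueError("implicit and plain level-indicator lists overlap")

    def __getattr__(self, name: str) -> frozenset[str]:
        try:
            return self.sets[name]
        except KeyError:
            raise AttributeError(name) from None

    # Derived unions used by the pattern files ----------------------------
    @property
    def scale_indicators(self) -> frozenset[str]:
        return self.sets["si_high"] | self.sets["si_low"]

    @property
    def level_indicators(self) -> frozenset[str]:
        return (
            self.sets["li_implicit_high"]
            | self.sets["li_implicit_low"]
            | self.sets["li_plain_high"]
            | self.sets["li_plain_low"]
        )

    @property
    def high_triggers(self) -> frozenset[str]:
        return self.sets["si_high"] | self.sets["li_implicit_high"] | self.sets["li_plain_high"]

    @property
    def low_triggers(self) -> frozenset[str]:
        return self.sets["si_low"] | self.sets["li_implicit_low"] | self.sets["li_plain_low"]

    @property
    def separators(self) -> frozenset[str]:
        base = self.sets["entity_separators"]
        if self.extended_separators:
            base = base | self.sets["entity_separators_extended"]
        return base

    @property
    def prefilter_lemmas(self) -> frozenset[str]:
        """Single-token lemmas whose presence makes a sentence worth parsing."""
        return self.scale_indicators | self.level_indicators | self.sets["expression_nouns"]

    def resolve(self, name: str) -> frozenset[str]:
        """Look up a (possibly derived) lexicon by name, for the pattern DSL."""
        derived = {
            "scale_indicators": self.scale_indicators,
            "level_indicators": self.level_indicators,
            "high_triggers": self.high_triggers,
            "low_triggers": self.low_triggers,
            "separators": self.separators,
        }
        if name in derived:
            return derived[name]
        if name in self.sets:
            return self.sets[name]
        raise KeyError(f"unknown lexicon: {name}")


def load_triggers(path: str | Path | None = None, *, extended_separators: bool = False) -> TriggerLexicons:
    p = Path(path) if path is not None else _data_path("triggers.yaml")
    raw = yaml.safe_load(p.read_text(encoding="utf-8"))
    sets = {k: frozenset(str(v).lower() for v in raw.get(k, [])) for k in _TRIGGER_KEYS}
    return TriggerLexicons(sets=sets, extended_separators=extended_separators)


class NameLexicon:
    """Case-insensitive surface-form -> identifier map with longest-match lookup.

    Keys are stored as tuples of lowercase lemma tokens so that plural surface
    forms ("ovarian cancers") hit singular entries ("ovarian cancer").
    """

    def __init__(self, entries: dict[str, str]):
        self._by_tokens: dict[tuple[str, ...], str] = {}
        for name, ident in entries.items():
            key = tuple(name.lower().split())
            self._by_tokens[key] = ident
        self.max_len = max((len(k) for k in self._by_tokens), default=1)

    def __len__(self) -> int:
        return len(self._by_tokens)

    def get(self, tokens: tuple[str, ...]) -> str | None:
        return self._by_tokens.get(tuple(t.lower() for t in tokens))

    def add(self, name: str, ident: str) -> None:
        key = tuple(name.lower().split())
        self._by_tokens[key] = ident
        self.max_len = max(self.max_len, len(key))


def _load_tsv_map(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) >= 2 and row[0].strip():
                out[row[0].strip()] = row[1].strip()
    return out


def load_gene_lexicon(path: str | Path | None = None) -> NameLexicon:
    p = Path(path) if path is not None else _data_path("gene_lexicon.tsv")
    return NameLexicon(_load_tsv_map(p))


def load_disease_lexicon(path: str | Path | None = None) -> NameLexicon:
    p = Path(path) if path is not None else _data_path("disease_lexicon.tsv")
    return NameLexicon(_load_tsv_map(p))


def load_medic_doid_map(path: str | Path | None = None) -> dict[str, str]:
    """MEDIC (MeSH/OMIM) identifier -> DOID mapping table."""
    p = Path(path) if path is not None else _data_path("medic_doid.tsv")
    return _load_tsv_map(p)
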