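"""The curatable output record and its (de)serialization.

One ``ExpressionRecord`` is one row a curator could load into an expression
database: which gene or microRNA, expressed High or Low, in which disease
(normalized to a DOID), in which sample, compared against what, and whether
the comparison baseline was a normal/control sample.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

FRAMES = ("Control", "Control_Implicit", "Not_Control", "none")
DISEASE_SOURCES = ("sentence", "title", "first", "conclusion", "investigation", "analyzed")


@dataclass(frozen=True)
class ExpressionRecord:
    pmid: str
    sentence_index: int
    sentence_text: str
    relation_type: str  # "A" or "B"
    entity_text: str
    entity_kind: str  # "gene" | "mirna"
    gene_id: str | None  # NCBI Gene ID (genes only)
    mirna_norm: str | None  # canonical miRNA name (miRNAs only)
    level: str  # "High" | "Low"
    disease_text: str | None
    doid: str | None
    disease_sample: str | None
    compared_sample: str | None  # Type A only
    frame_of_reference: str
    disease_source: str | None

    def __post_init__(self) -> None:
        if self.relation_type not in ("A", "B"):
            raise ValueError(f"relation_type must be A or B, got {self.relation_type!r}")
        if self.level not in ("High", "Low"):
            raise ValueError(f"level must be High or Low, got {self.level!r}")
        if self.frame_of_reference not in FRAMES:
            raise ValueError(f"bad frame_of_reference {self.frame_of_reference!r}")
        if (self.gene_id is None) == (self.mirna_norm is None):
            raise ValueError("exactly one of gene_id/mirna_norm must be set")
        if (self.compared_sample is not None) and self.relation_type != "A":
            raise ValueError("compared_sample is only defined for Type A relations")
        if self.frame_of_reference == "Control_Implicit" and self.relation_type != "B":
            raise ValueError("Control_Implicit applies to Type B relations only")
        if self.disease_source is not None and self.disease_source not in DISEASE_SOURCES:
            raise ValueError(f"bad disease_source {self.disease_source!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExpressionRecord":
        known = {f.name for f in fields(cls)}
        clean = {k: v for k, v in d.items() if k in known}
        if isinstance(clean.get("sentence_index"), str):
            clean["sentence_index"] = int(clean["sentence_index"])
        for k in ("gene_id", "mirna_norm", "disease_text", "doid", "disease_sample",
                  "compared_sample", "disease_source"):
            if clean.get(k) == "":
                clean[k] = None
        return cls(**clean)

    def key(self, components: tuple[str, ...]) -> tuple:
        """Projection used by the scorer; 'entity' means the normalized id."""
        out = []
        for c in components:
            if c == "entity":
                out.append(self.gene_id if self.gene_id is not None else self.mirna_norm)
            elif c == "frame":
                out.append(self.frame_of_reference)
            else:
                out.append(getattr(self, c))
        return tuple(out)


_FIELDS = [f.name for f in fields(ExpressionRecord)]


def write_records(records: list[ExpressionRecord], path: str | Path, format: str = "jsonl") -> None:
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                fh.write(json.dumps(r.to_dict(), ensure_ascii=False) + "\n")
    elif format == "tsv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_FIELDS, delimiter="\t")
            w.writeheader()
            for r in records:
                row = {k: ("" if v is None else v) for k, v in r.to_dict().items()}
                w.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_records(path: str | Path, format: str | None = None) -> list[ExpressionRecord]:
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix == ".tsv" else "jsonl"
    out: list[ExpressionRecord] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    out.append(ExpressionRecord.from_dict(json.loads(line)))
    elif format == "tsv":
        with path.open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                out.append(ExpressionRecord.from_dict(row))
    else:
        raise ValueError(f"unknown format {format!r}")
    return out
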