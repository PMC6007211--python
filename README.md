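# gexmine

Rule-based mining of **gene and microRNA differential-expression statements
in disease contexts** from biomedical abstracts.

Small-scale studies report results like *"Expression of Shp2 protein was
significantly upregulated in Oral Squamous Cell Carcinoma (OSCC) tissues
compared with the normal tissues"* thousands of times across Medline.
Curators of expression databases (tumor-vs-normal resources in particular)
need these statements as structured rows: which gene, up or down, in which
disease, in which sample, against which baseline. `gexmine` extracts exactly
that, offline, from abstract collections.

## What it extracts

Two statement types are curated:

- **Type A — explicit comparisons.** `X higher/lower/increased… in S1
  than/compared-with S2`. The components are the **scale indicator (SI)**
  ("higher"), the **compared aspect (CA)** ("Expression of Shp2 protein"),
  the two **compared entities (CE1, CE2)** ("OSCC tissues", "normal
  tissues") and the **entity separator (ES)** ("compared with"), which is
  verified but not emitted.
- **Type B — plain level statements.** `X over-expressed/high/low in S`.
  Components: **level indicator (LI)**, **expressed aspect (EA)**,
  **expressed location (EL)**. Directional LIs ("over-expressed",
  "increased", "higher") imply an unstated baseline and set an
  *implicit-comparison* flag; plain "high"/"low" do not.

Statements linking expression to outcomes or processes ("over-expression of
X *enhanced invasion*") are recognized and deliberately **not** curated.

Each extracted relation is filtered by argument type (the CA/EA must be an
expression phrase or the gene itself; CEs/EL must be disease samples) and
assembled into a record: entity (NCBI Gene ID or canonical miRNA name),
level (`High`/`Low`), associated disease (DOID), disease sample, compared
sample, and a **frame-of-reference** flag — `Control`, `Control_Implicit`,
`Not_Control`, or `none`. When the sentence only says "cancer tissues", the
disease is inferred from the abstract context (title, first sentence,
investigation-aim sentences, patient-enrollment sentences, conclusion).

Extraction runs over enhanced dependency graphs (preposition-collapsed
`nmod:in`-style labels, conjunct propagation) produced by a deterministic
rule-based parser, and the construction inventory lives in editable YAML
pattern files matched by a small subgraph-matching engine.

## Worked example

```python
from gexmine import assemble, build_abstract

abstract = build_abstract(
    "24439919",
    "Shp2 expression in oral squamous cell carcinoma.",
    "Expression of Shp2 protein was significantly upregulated in "
    "Oral Squamous Cell Carcinoma (OSCC) tissues compared with the normal tissues.",
)
for record in assemble(abstract):
    print(record.to_dict())
```

prints (abridged):

```
{'pmid': '24439919', 'relation_type': 'A', 'entity_text': 'Shp2',
 'gene_id': '5781', 'level': 'High', 'doid': 'DOID:0050866',
 'disease_sample': 'OSCC tissues', 'compared_sample': 'normal tissues',
 'frame_of_reference': 'Control', 'disease_source': 'sentence', ...}
```

i.e. Shp2 (NCBI Gene ID 5781) is expressed **High** in oral squamous cell
carcinoma (DOID:0050866) tissue relative to an explicit normal-tissue
control — a row ready for a tumor-vs-normal expression database. The
`Control`/`Control_Implicit` frames are exactly the records the bundled
cancer-relevance filter (`--bioxpress`, DOID:162 subtree) keeps.

## Command line

```bash
gexmine fixtures -n 200 --seed 1 --out corpus      # synthetic corpus + gold
gexmine extract corpus.tsv -o pred.jsonl           # run the pipeline
gexmine score corpus.gold.jsonl pred.jsonl \
    --components pmid,entity,level,doid,frame      # exact-match scoring
gexmine extract corpus.tsv -o bx.jsonl --bioxpress # cancer-vs-control only
gexmine report pred.jsonl                          # per-entity counts
```

`extract` reads Medline/PubMed XML, `pmid<TAB>title<TAB>abstract` TSV, or a
directory of plain-text files. The scorer counts an instance as a true
positive only when every requested component matches; on the synthetic
corpus above it prints `{"tp": ..., "fp": 0, "fn": 0, "precision": 100.0,
"recall": 100.0, "f": 100.0}`.

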