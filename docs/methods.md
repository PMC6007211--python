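# Methods

## Extraction model

The pipeline treats differential-expression curation as relation extraction
over dependency graphs, in five stages:

1. **Text processing.** Abstracts are NFKC-normalized, sentence-split
   (abbreviation-protected; the title is sentence index 0) and tokenized
   with 0-based half-open character offsets. Sentences without at least one
   expression/comparison trigger lemma are not parsed further (prefilter).
   Structured-abstract labels (`METHODS:` …) are preserved as section hints;
   without labels, the first body sentence is `FIRST` and the last two are
   `CONCLUSION`.
2. **Syntactic processing.** A deterministic rule-based parser produces
   *enhanced* dependencies directly: prepositions collapse into the edge
   label (`nmod:in`, `nmod:of` …), an entity introduced by an
   entity-separator phrase gets the dedicated label `nmod:es`, and conjunct
   propagation copies a coordination head's incoming edges onto each
   conjunct (flagged, so span computations can ignore the copies). The
   canonical label set (`nsubj`, `nsubj:pass`, `obj`, `amod`, `compound`,
   `nmod:<prep>`, `conj`, …) is fixed; an alias table maps dialect names
   (`nsubjpass`, `dobj`, `prep_in`) onto it, so a different parser can be
   substituted behind the same adapter surface without touching patterns.
3. **Entity detection.** MicroRNAs by a regex family following the miRBase
   convention (optional species prefix, stem `miR|miRNA|microRNA|let`,
   number, letter suffix, variant, arm suffix); the canonical form drops the
   species prefix and arm (kept in a secondary field), e.g.
   `hsa-miR-1-3p → mir-1` (+`3p`). Elided coordinated stems
   ("miR-143 and **-195**") inherit the stem of the preceding conjunct.
   Genes and diseases by case-insensitive longest lemma-n-gram lookup in
   bundled TSV lexicons (genes → NCBI Gene IDs, diseases → DOIDs); genes and
   proteins are not distinguished. Parenthetically defined abbreviations
   are linked per abstract (Schwartz–Hearst-style right-to-left character
   check), so "OSCC" inherits the DOID of its long form. A reader for
   precomputed PubTator-offset annotation files is provided as an
   alternative tagger; MEDIC disease identifiers map to DOIDs through a
   bundled table.
4. **Relation extraction.** Declarative patterns (YAML; node constraints on
   lemma/POS/lexicon membership, edge constraints as label regexes) are
   matched by a backtracking subgraph matcher with deterministic output
   order. The Type A inventory covers: SI as main predicate (comparative
   adjective or directional verb, with the fronted-separator variant),
   first CE attached to the CA's own NP ("expression of X *in CE1* was
   higher than that in CE2"), observation-verb predicates with the SI as a
   noun modifier, and CE-as-subject with the CA as object. A plain
   `nmod:in`/`nmod:in` CE pair is accepted only when a complete
   entity-separator phrase stands between the two entities. Type B covers
   LI-as-predicate, observation-verb with LI modifying the EA, and agentive
   subjects ("We found high … of X in Y"). Negated triggers are dropped.
   A trigger consumed by a full comparison never also yields a Type B
   relation (comparison precedence); an implicit-class trigger without a CE
   pair falls through to Type B.
5. **Assembly.** Argument-type filtering, gene/level/disease extraction,
   frame-of-reference classification, and record emission with provenance
   (PMID, sentence index, sentence text) plus a reason-code log for every
   dropped relation.

## Tunable parameters and defaults

All trigger lists live in `gexmine/data/triggers.yaml` and are overridable
per run (`--lexicon-dir`). The ones that matter most:

- **Entity separators** default to {than, compared to/with, in comparison
  to/with, versus, vs, relative to}. Temporal separators ("after",
  "following") describe before/after-treatment comparisons rather than
  sample contrasts and ship as an opt-in extension (`--extended-separators`).
- **Scale/level indicators** are split four ways: directional comparatives
  and verbs (si/li-implicit, e.g. higher, increased, over-expressed) versus
  plain adjectives (high, low). Direction maps to `High`/`Low`; the
  implicit/plain split drives the implicit-comparison flag. Comparative
  adjectives keep their comparative lemma ("higher" ≠ "high") precisely so
  this split survives lemmatization.
- **Control modifiers** {control, normal, healthy, adjacent, …} classify a
  compared entity as the baseline; **disease-sample heads** include bare
  organ nouns (ovary, brain, …) because samples like "normal ovaries" head
  on the organ word.
- **Context-inference order** is title → first sentence → investigation
  sentences → enrollment/setup sentences → conclusion (last two sentences;
  the conclusion step can be disabled). Investigation sentences need an
  investigation trigger plus an author/purpose agent or passive voice;
  setup sentences need a passive analyzed-trigger and a count in the theme
  (digits or number words). When several qualifying sentences disagree, the
  most frequent DOID wins, ties broken by the precedence order — single
  disease mentions in unqualified mid-abstract sentences are never used.

## Numerical and span conventions

- **Scoring.** An instance is a true positive only if every configured
  component matches. Precision and recall are *truncated* to two decimals;
  the F-score is computed from the exact values and *rounded*. This mixed
  convention is the one that reproduces the reference arithmetic for
  TP 77 / FP 5 / FN 15 (93.90 / 83.69 / 88.51) exactly; no single
  truncate-or-round rule does.
- **Spans.** NP yields follow determiners, modifiers, compounds and
  of-/with-complements, never cross entity-separator tokens, and are the
  maximal contiguous run around the head. The CA span of a comparison
  excludes the SI token ("Higher **miR-210 expression**"); the EA span of a
  plain-level statement excludes plain-class LIs ("High **TRIM32 expression
  levels**") but keeps comparative ones ("**Higher level of BRF2
  expression**") — the convention that matches all worked examples, which
  are not internally uniform on this point. Sample strings drop leading
  determiners and collapse a linked long-form/abbreviation pair to the
  short form ("… (OSCC) tissues" → "OSCC tissues").
- **Tie-breaks.** Several bindings for one SI keep the CE pair nearest the
  trigger; several ELs for one (LI, EA) keep the nearest EL. Anaphoric
  "that" heads ("higher than **that** in Ta carcinomas") keep their
  in-complement in the span and type-check through it.
- **Degenerate inputs.** Parsing is total: unattachable tokens hang off the
  root, clauses split at semicolons join by `parataxis`, and a parser
  failure skips the sentence with a logged reason, never the abstract.

## Design choices on genuinely open points

- **Both CEs diseased** (`Not_Control`): CE1 is reported as the disease
  sample and CE2 as the compared sample, and the disease is read from CE1.
- **Both CEs with control modifiers**: ambiguous; classified `Not_Control`.
- **Multi-relation sentences**: all non-overlapping matches are emitted;
  a coordinated CA/EA replicates the relation once per conjunct.
- **Records without a resolvable DOID** are emitted flagged (absent norm)
  rather than dropped — the cancer-relevance filter excludes them later,
  but curators see the near-misses.
- The relevance filter keeps records whose DOID lies in the cancer subtree
  (DOID:162, transitive `is_a` closure) **and** whose frame is `Control` or
  `Control_Implicit`. A synthetic miniature ontology slice ships for
  offline tests; point `--do-obo` at a full release in production.

## What the synthetic corpus does and does not show

The fixture generator emits abstracts whose relation sentences instantiate
the covered construction families (P1–P5 comparative, Q1–Q3 plain-level),
plus consequence-statement and trigger-free distractors, and
context-inference variants (generic "cancer tissues" with the disease only
in the title or in a METHODS sentence with a patient count). Slot fillers
come from the bundled lexicons; generation is deterministic in the seed.
Test sizes: 200 abstracts for the exact-recovery check, 150 for the
invariant sweep, 50 for the brute-force pattern-oracle comparison (all
graphs ≤ 12 nodes; the oracle enumerates every node assignment).

Exact precision/recall of 1.0 on this corpus demonstrates that parser,
patterns, typing, inference and assembly compose correctly on the
constructions the system claims to cover. It does **not** estimate recall
on arbitrary prose: real abstracts contain cross-clause comparisons,
anaphora, unseen trigger variants, and parse-degrading syntax that the
generator deliberately excludes.

## Known limitations

- Comparisons whose two compared entities sit in different clauses are not
  connected (clauses parse independently); anaphoric aspects ("the same
  microRNAs were detected …") are not resolved — both are out of scope by
  design.
- The rule-based parser targets the declarative results-sentence register;
  heavily embedded or interrogative sentences get best-effort flat
  attachments and usually no relation rather than a wrong one.
- Bundled gene/disease lexicons are deliberately small curated tables meant
  for testing and as format references; production use should supply
  organism-scale lexicons or PubTator-offset annotation files.
- Quantitative magnitudes ("twofold higher") are dropped; only direction is
  kept.
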