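# Trigger lexicons. All entries are lowercase lemmas (multi-word phrases are
# space-joined lemmas). The shipped lists contain every trigger quoted in the
# package documentation plus conservative same-class extensions; every list is
# user-extensible by pointing --lexicon-dir at an edited copy.

# Head nouns that type a noun phrase as an *expression* phrase.
expression_nouns:
  - expression
  - level
  - over-expression
  - overexpression
  - under-expression
  - underexpression
  - up-regulation
  - upregulation
  - down-regulation
  - downregulation
  - amount
  - abundance

# Scale indicators for comparative (Type A) statements, by direction.
si_high:
  - higher
  - greater
  - increase
  - elevate
  - raise
  - up-regulate
  - upregulate
  - over-express
  - overexpress
si_low:
  - lower
  - smaller
  - decrease
  - reduce
  - diminish
  - decline
  - down-regulate
  - downregulate
  - under-express
  - underexpress

# Level indicators for non-comparative (Type B) statements. The implicit class
# carries an implied baseline ("over-expressed", "increased", "higher"); the
# plain class ("high", "low") states a level without implying a comparison.
li_implicit_high:
  - over-express
  - overexpress
  - up-regulate
  - upregulate
  - increase
  - elevate
  - amplify
  - higher
  - greater
li_implicit_low:
  - under-express
  - underexpress
  - down-regulate
  - downregulate
  - decrease
  - reduce
  - diminish
  - decline
  - lower
  - smaller
li_plain_high:
  - high
  - abundant
  - strong
li_plain_low:
  - low
  - weak
  - minimal
  - absent

# Entity separators: phrases that separate the two compared entities.
entity_separators:
  - than
  - compared to
  - compared with
  - in comparison to
  - in comparison with
  - in comparison
  - relative to
  - versus
  - vs
  - vs.
# Opt-in temporal separators (before/after-treatment comparisons); off by
# default because they describe a time course rather than a sample contrast.
entity_separators_extended:
  - after
  - following

# Head nouns that type a noun phrase as a disease sample.
disease_sample_heads:
  - tissue
  - cell
  - line
  - patient
  - sample
  - specimen
  - tumor
  - tumour
  - control
  - individual
  - subject
  - case
  - group
  - cohort
  - biopsy
  - serum
  - plasma
  - blood
  - mucosa
  - man
  - woman
  # bare organ nouns; required for samples such as "normal ovaries"
  - ovary
  - brain
  - lung
  - liver
  - breast
  - colon
  - kidney
  - prostate
  - stomach
  - pancreas
  - skin
  - thyroid

# Generic disease words: type as disease-sample but carry no identity, so the
# associated disease must be inferred from elsewhere in the abstract.
generic_disease_phrases:
  - tumor
  - tumour
  - cancer
  - carcinoma
  - disease
  - malignancy
  - neoplasm
  - lesion

# Noun modifiers marking a compared entity as the normal/control baseline.
control_modifiers:
  - control
  - normal
  - healthy
  - adjacent
  - non-cancerous
  - noncancerous
  - non-tumor
  - nontumor
  - non-tumour
  - cancer-free
  - benign
  - non-malignant
  - nonmalignant

# Agents and purposes that license an investigation sentence.
agent_words:
  - we
  - author
  - investigator
  - researcher
  - study
purpose_words:
  - aim
  - objective
  - purpose
  - goal

# Verbs that announce the investigational aim of the work.
investigation_triggers:
  - investigate
  - examine
  - analyze
  - analyse
  - evaluate
  - study
  - compare

# Verbs describing the experimental set-up (theme = patients/samples).
analyzed_triggers:
  - test
  - enroll
  - enrol
  - recruit
  - collect
  - analyze
  - analyse
  - measure
  - explore
  - assess
  - obtain
  - include

# Predicate classes used by the extraction patterns.
observation_verbs:
  - find
  - observe
  - detect
  - note
  - identify
report_verbs:
  - present
  - show
  - exhibit
  - display
  - demonstrate
  - reveal
  - have
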