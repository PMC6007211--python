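# Comparison (Type A) extraction patterns over canonical enhanced dependencies.
# Variables: si = scale indicator, ca = compared-aspect head, cex/cey = the two
# compared-entity heads (oriented into CE1/CE2 afterwards: an entity attached
# through an entity-separator phrase is CE2, otherwise surface order decides,
# and a plain nmod:in pair must be separated by an entity-separator token).

- name: a_si_predicate
  family: P1
  nodes:
    si: {lexicon: scale_indicators, pos: "JJR|JJ|VBN|VBD"}
    ca: {}
    cex: {}
    cey: {}
  edges:
    - [si, ca, "nsubj(:pass)?"]
    - [si, cex, "nmod:in"]
    - [si, cey, "nmod:(in|es)"]
  distinct:
    - [cex, cey]
  result: [si, ca, cex, cey]

# SI is the main predicate but the first compared entity hangs off the
# compared-aspect NP itself ("the expression of X in CE1 was higher than
# that in CE2").
- name: a_si_subject_np
  family: P2
  nodes:
    si: {lexicon: scale_indicators, pos: "JJR|JJ|VBN|VBD"}
    ca: {}
    cex: {}
    cey: {}
  edges:
    - [si, ca, "nsubj(:pass)?"]
    - [ca, cex, "nmod:in"]
    - [si, cey, "nmod:(in|es)"]
  distinct:
    - [cex, cey]
  result: [si, ca, cex, cey]

# Observation-verb predicate with the SI as a noun modifier of the CA
# ("Higher X expression was found in CE1 compared to CE2").
- name: a_observation_verb
  family: P3
  nodes:
    pred: {lexicon: observation_verbs, pos: "VBN|VBD|VBZ|VBP|VB"}
    si: {lexicon: scale_indicators}
    ca: {}
    cex: {}
    cey: {}
  edges:
    - [pred, ca, "nsubj(:pass)?"]
    - [ca, si, "amod"]
    - [pred, cex, "nmod:in"]
    - [pred, cey, "nmod:(in|es)"]
  distinct:
    - [cex, cey]
  result: [si, ca, cex, cey]

# Compared entity as subject, CA as object of a report verb, fronted
# entity-separator phrase carrying CE2 ("Compared to controls, patients
# with CLL presented a lower expression level of X").
- name: a_ce_subject
  family: P5
  nodes:
    pred: {lexicon: report_verbs, pos: "VBD|VBZ|VBP|VB|VBN"}
    si: {lexicon: scale_indicators}
    ca: {}
    cex: {}
    cey: {}
  edges:
    - [pred, cex, "nsubj"]
    - [pred, ca, "obj"]
    - [ca, si, "amod"]
    - [pred, cey, "nmod:es"]
  distinct:
    - [cex, cey]
  result: [si, ca, cex, cey]
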