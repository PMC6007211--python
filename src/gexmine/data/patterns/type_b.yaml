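# Non-comparative (Type B) extraction patterns.
# Variables: li = level indicator, ea = expressed-aspect head, el = expressed-
# location head. A sentence whose trigger already anchors a full comparison is
# consumed by the Type A extractor first (precedence handled downstream).

# LI is the main predicate ("X is over-expressed in Y", "levels were low in Y").
- name: b_li_predicate
  family: Q1
  nodes:
    li: {lexicon: level_indicators, pos: "JJ|JJR|VBN|VBD"}
    ea: {}
    el: {}
  edges:
    - [li, ea, "nsubj(:pass)?"]
    - [li, el, "nmod:in"]
  result: [li, ea, el]

# Observation-verb predicate, LI modifies the EA head ("Higher level of X
# expression was found in Y", "High X levels were detected in Y").
- name: b_observation_verb
  family: Q2
  nodes:
    pred: {lexicon: observation_verbs, pos: "VBN|VBD|VBZ|VBP|VB"}
    li: {lexicon: level_indicators}
    ea: {}
    el: {}
  edges:
    - [pred, ea, "nsubj(:pass)?"]
    - [ea, li, "amod"]
    - [pred, el, "nmod:in"]
  result: [li, ea, el]

# Agentive subject ("We found high expression levels of X in Y"): the object
# of the predicate is the EA; the EL attaches to the predicate or to the EA.
- name: b_agentive_pred_el
  family: Q3
  nodes:
    pred: {lexicon: observation_verbs, pos: "VBD|VBZ|VBP|VB|VBN"}
    agent: {lexicon: agent_words}
    li: {lexicon: level_indicators}
    ea: {}
    el: {}
  edges:
    - [pred, agent, "nsubj"]
    - [pred, ea, "obj"]
    - [ea, li, "amod"]
    - [pred, el, "nmod:in"]
  result: [li, ea, el]

- name: b_agentive_ea_el
  family: Q3
  nodes:
    pred: {lexicon: observation_verbs, pos: "VBD|VBZ|VBP|VB|VBN"}
    agent: {lexicon: agent_words}
    li: {lexicon: level_indicators}
    ea: {}
    el: {}
  edges:
    - [pred, agent, "nsubj"]
    - [pred, ea, "obj"]
    - [ea, li, "amod"]
    - [ea, el, "nmod:in"]
  result: [li, ea, el]
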