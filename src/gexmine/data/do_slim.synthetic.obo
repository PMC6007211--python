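format-version: 1.2
ontology: doid-slim-synthetic
remark: Synthetic miniature slice of the Disease Ontology is_a hierarchy, built
remark: for offline tests of the cancer-subtree relevance filter. It contains a
remark: cancer subtree rooted at DOID:162 plus non-cancer decoy terms. It is a
remark: constructed stand-in, not an export of the real ontology release.

[Term]
id: DOID:4
name: disease

[Term]
id: DOID:7
name: disease of anatomical entity
is_a: DOID:4

[Term]
id: DOID:14566
name: disease of cellular proliferation
is_a: DOID:4

[Term]
id: DOID:162
name: cancer
is_a: DOID:14566

[Term]
id: DOID:0050686
name: organ system cancer
is_a: DOID:162

[Term]
id: DOID:2394
name: ovarian cancer
is_a: DOID:0050686

[Term]
id: DOID:9256
name: colorectal cancer
is_a: DOID:0050686

[Term]
id: DOID:219
name: colon cancer
is_a: DOID:9256

[Term]
id: DOID:1793
name: pancreatic cancer
is_a: DOID:0050686

[Term]
id: DOID:10534
name: gastric cancer
is_a: DOID:0050686

[Term]
id: DOID:1324
name: lung cancer
is_a: DOID:0050686

[Term]
id: DOID:3908
name: non-small cell lung carcinoma
is_a: DOID:1324

[Term]
id: DOID:5409
name: small cell lung carcinoma
is_a: DOID:1324

[Term]
id: DOID:1612
name: breast cancer
is_a: DOID:0050686

[Term]
id: DOID:3459
name: breast carcinoma
is_a: DOID:1612

[Term]
id: DOID:10283
name: prostate cancer
is_a: DOID:0050686

[Term]
id: DOID:684
name: hepatocellular carcinoma
is_a: DOID:3571

[Term]
id: DOID:3571
name: liver cancer
is_a: DOID:0050686

[Term]
id: DOID:1909
name: melanoma
is_a: DOID:162

[Term]
id: DOID:11054
name: urinary bladder cancer
is_a: DOID:0050686

[Term]
id: DOID:2671
name: transitional cell carcinoma
is_a: DOID:162

[Term]
id: DOID:0060108
name: brain glioma
is_a: DOID:162

[Term]
id: DOID:3068
name: glioblastoma
is_a: DOID:0060108

[Term]
id: DOID:0050866
name: oral squamous cell carcinoma
is_a: DOID:162

[Term]
id: DOID:1040
name: chronic lymphocytic leukemia
is_a: DOID:1240

[Term]
id: DOID:1240
name: leukemia
is_a: DOID:162

[Term]
id: DOID:0060058
name: lymphoma
is_a: DOID:162

[Term]
id: DOID:707
name: B-cell lymphoma
is_a: DOID:0060058

[Term]
id: DOID:3948
name: adrenocortical carcinoma
is_a: DOID:162

[Term]
id: DOID:4362
name: cervical cancer
is_a: DOID:0050686

[Term]
id: DOID:5041
name: esophageal cancer
is_a: DOID:0050686

[Term]
id: DOID:4450
name: renal cell carcinoma
is_a: DOID:0050686

[Term]
id: DOID:3347
name: osteosarcoma
is_a: DOID:162

[Term]
id: DOID:1781
name: thyroid cancer
is_a: DOID:0050686

[Term]
id: DOID:3969
name: papillary thyroid carcinoma
is_a: DOID:1781

[Term]
id: DOID:1380
name: endometrial cancer
is_a: DOID:0050686

[Term]
id: DOID:0050860
name: colon adenoma
is_a: DOID:4

[Term]
id: DOID:2043
name: hepatitis B
is_a: DOID:4

[Term]
id: DOID:5844
name: myocardial infarction
is_a: DOID:7

[Term]
id: DOID:9351
name: diabetes mellitus
is_a: DOID:4

[Term]
id: DOID:10652
name: Alzheimer's disease
is_a: DOID:4

[Term]
id: DOID:2841
name: asthma
is_a: DOID:7
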