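oral squamous cell carcinoma	DOID:0050866
ovarian cancer	DOID:2394
ovarian carcinoma	DOID:2394
colorectal cancer	DOID:9256
colorectal carcinoma	DOID:9256
pancreatic cancer	DOID:1793
gastric cancer	DOID:10534
stomach cancer	DOID:10534
lung cancer	DOID:1324
lung carcinoma	DOID:1324
non-small cell lung carcinoma	DOID:3908
non-small cell lung cancer	DOID:3908
nsclc	DOID:3908
small cell lung carcinoma	DOID:5409
breast cancer	DOID:1612
breast carcinoma	DOID:3459
prostate cancer	DOID:10283
hepatocellular carcinoma	DOID:684
liver cancer	DOID:3571
melanoma	DOID:1909
bladder cancer	DOID:11054
bladder carcinoma	DOID:11054
bladder urothelial carcinoma	DOID:11054
urothelial carcinoma	DOID:2671
glioma	DOID:0060108
high grade glioma	DOID:0060108
hgg	DOID:0060108
glioblastoma	DOID:3068
chronic lymphocytic leukemia	DOID:1040
cll	DOID:1040
leukemia	DOID:1240
lymphoma	DOID:0060058
adrenocortical carcinoma	DOID:3948
adrenocortical tumor	DOID:3948
colon cancer	DOID:219
colon adenoma	DOID:0050860
cervical cancer	DOID:4362
esophageal cancer	DOID:5041
renal cell carcinoma	DOID:4450
osteosarcoma	DOID:3347
thyroid cancer	DOID:1781
papillary thyroid carcinoma	DOID:3969
endometrial cancer	DOID:1380
b-cell lymphoma	DOID:707
hepatitis b	DOID:2043
chronic hepatitis b	DOID:2043
myocardial infarction	DOID:5844
diabetes mellitus	DOID:9351
alzheimer disease	DOID:10652
asthma	DOID:2841
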