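shp2	5781
ptpn11	5781
egfr	1956
gpc5	2262
pten	5728
tp	1890
tymp	1890
pdecgf	1890
foxd3	27022
galnt2	2590
igf1r	3480
brf2	55290
trim32	22954
fkbp51	2289
fkbp5	2289
gcs	7357
ugcg	7357
c1galt1	56913
lef1	51176
nampt	10135
tp53	7157
kras	3845
myc	4609
braf	673
met	4233
vegfa	7422
cdh1	999
mmp9	4318
timp1	7076
bcl2	596
stat3	6774
akt1	207
notch1	4851
ctnnb1	1499
muc1	4582
b4galt1	2683
st6gal1	6480
mgat5	4249
fut8	2530
ercc1	2067
her2	2064
erbb2	2064
survivin	332
birc5	332
cyclin d1	595
ccnd1	595
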