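MESH:D009369	DOID:162
MESH:D002294	DOID:0050866
MESH:D010051	DOID:2394
MESH:D015179	DOID:9256
MESH:D010190	DOID:1793
MESH:D013274	DOID:10534
MESH:D008175	DOID:1324
MESH:D002289	DOID:3908
MESH:D001943	DOID:1612
MESH:D011471	DOID:10283
MESH:D006528	DOID:684
MESH:D008545	DOID:1909
MESH:D001749	DOID:11054
MESH:D005910	DOID:0060108
MESH:D015451	DOID:1040
MESH:D003110	DOID:219
MESH:D006509	DOID:2043
MESH:D009203	DOID:5844
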