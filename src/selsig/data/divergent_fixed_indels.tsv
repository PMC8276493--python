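chrom	pos_bp	low	high	region	gene	mutation
9	48280960	1/1	2/2	3'UTR	MC2R	3-bp deletion
11	56199847	0/0	1/1	Frameshift	TTC23L	2-bp deletion
12	138684799	1/1	0/0	Frameshift	ENSOCUG00000031631	2-bp deletion
12	138685173	1/1	0/0	Frameshift	ENSOCUG00000031631	1-bp insertion
12	138685179	1/1	0/0	Frameshift	ENSOCUG00000031631	2-bp deletion
14	33195918	1/1	2/2	3'UTR	ENSOCUG00000006264	25-bp deletion
15	4723998	1/1	0/0	3'UTR	SLC18A1	4-bp deletion
19	40686575	0/0	1/1	5'UTR	FBXL20	90-bp insertion
19	43006505	0/0	1/1	Frameshift	GHDC	2-bp deletion
19	44276359	1/1	0/0	3'UTR	CD300LG	8-bp deletion
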