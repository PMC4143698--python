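gene	chrom	genic	flanking
ADM	11	30	1423
ADRA1B	5	520	4433
AGT	1	165	401
AGTR1	3	417	12215
ATP2C1	3	1131	801
CALCA	11	54	1521
CAV1	7	348	982
CHRNB1	17	126	0
CLIC4	1	653	1195
CNGA4	11	46	93
DRD3	3	451	764
ECE1	1	1069	1431
EDNRB	13	388	1120
GCHFR	15	29	65
ITPR1	3	3567	741
KNG1	3	331	744
MYLK	3	2022	183
NOS3	7	200	87
NOSIP	19	227	145
NPPB	1	31	821
NPR1	1	123	418
PDE3B	11	1445	19
PTGS1	9	299	973
PTGS2	1	70	2823
REN	1	114	235
S1PR1	1	55	2612
SLC7A1	13	939	1742
SPHK1	17	43	338
SPHK2	19	77	0
UTS2	1	65	675
UTS2R	17	30	244
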