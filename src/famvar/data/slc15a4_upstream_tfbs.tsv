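tf_name	targeting	matrix_id	rel_score	start	end	strand	site_seq
MEIS2	WT	MA0774.1	0.84	116	123	+	gggacAGG
NR1D2	WT	MA1532.1	0.81	108	122	+	tgggttctgggacAG
RARA::RXRG	WT	MA1149.1	0.80	109	126	+	gggttctgggacAGGTGA
RBPJ	WT	MA1116.1	0.86	113	122	+	tctgggacAG
RORC	WT	MA1151.1	0.82	110	121	+	ggttctgggacA
SREBF1	WT	MA0595.1	0.80	118	127	-	GTCACCTgtc
STAT1	WT	MA0137.2	0.84	109	123	-	CCTgtcccagaaccc
STAT1	WT	MA0137.3	0.88	111	121	+	gttctgggacA
TGIF2LX	WT	MA1571.1	0.81	117	128	-	GGTCACCTgtcc
TGIF2LX	WT	MA1571.1	0.81	117	128	+	ggacAGGTGACC
TGIF2LY	WT	MA1572.1	0.82	117	128	-	GGTCACCTgtcc
TGIF2LY	WT	MA1572.1	0.82	117	128	+	ggacAGGTGACC
GRHL2	MUT	MA1105.2	0.83	116	127	+	ggaacAGGTGAC
MYF6	MUT	MA0667.1	0.82	118	127	+	aacAGGTGAC
NFATC2	MUT	MA0152.1	0.90	115	121	-	Tgttcca
PRDM4	MUT	MA1647.1	0.81	114	124	-	ACCTgttccag
SCRT1	MUT	MA0743.1	0.83	114	128	+	ctggaacAGGTGACC
SCRT1	MUT	MA0743.2	0.85	113	128	+	tctggaacAGGTGACC
SCRT2	MUT	MA0744.1	0.85	114	126	+	ctggaacAGGTGA
SCRT2	MUT	MA0744.2	0.85	113	128	+	tctggaacAGGTGACC
TEF	MUT	MA0843.1	0.80	110	121	-	Tgttccagaacc
ZBTB26	MUT	MA1579.1	0.92	107	121	-	Tgttccagaacccag
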