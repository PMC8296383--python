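rsid	chrom	pos	major	minor	gene	consequence	maf
rs28399433	19	40850474	A	C	CYP2A6	upstream_2kb	0.10323
rs28399434	19	40850414	C	T	CYP2A6	missense	0.00003
rs8192720	19	40850405	G	A	CYP2A6	synonymous	0.02214
rs1137115	19	40850376	C	T	CYP2A6	synonymous	0.24442
rs1801272	19	40848628	A	T	CYP2A6	missense	0.01974
rs199916117	19	40848293	T	C	CYP2A6	missense	0.00058
rs148166815	19	40845404	A	G	CYP2A6	missense	0.00008
rs1809810	19	40844759	T	A	CYP2A6	missense	0.01259
rs2431413	19	40844073	A	G	CYP2A6	intron	0.12103
rs143731390	19	40843969	T	A	CYP2A6	missense	0.1020
rs5031016	19	40843869	A	G	CYP2A6	missense	0.00775
rs6413474	19	40843854	T	C	CYP2A6	missense	0.01235
rs5031017	19	40843845	C	A	CYP2A6	missense	0.00049
rs28399468	19	40843827	C	A	CYP2A6	missense	0.00165
rs10189159	2	50487433	T	C	NRXN1	intron	0.3286
rs985919	2	50459875	C	A	NRXN1	intron	0.4957
rs10865246	2	50443116	C	A	NRXN1	intron	0.4950
rs1882296	2	50039707	T	C	NRXN1	intron	0.3900
rs1800955	11	636784	T	C	DRD4	upstream_2kb	0.406
rs6311	13	46897343	C	T	HTR2A	upstream_2kb	0.3970
rs6313	13	46895805	G	A	HTR2A	synonymous	0.40701
rs12914385	15	78606381	C	T	CHRNA3	intron	0.3138
rs1317286	15	78603787	A	G	CHRNA3	intron	0.2974
rs6495307	15	78597979	C	T	CHRNA3	intron	0.310
rs615470	15	78593646	T	C	CHRNA3	intron	0.3688
rs16969968	15	78590583	G	A	CHRNA5	missense	0.26553
rs17408276	15	78589276	T	C	CHRNA5	intron	0.2881
rs951266	15	78586199	G	A	CHRNA5	intron	0.2522
rs680244	15	78578946	T	C	CHRNA5	intron	0.4098
rs17486278	15	78575140	A	C	CHRNA5	intron	0.3167
rs4105144	19	40852719	T	C	intergenic	intergenic	0.4412
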