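# Published per-cohort genotype counts for the 31-SNP panel, transcribed
# in the strand/letters the source tables print (opposite strand to the
# panel file for several SNPs).  Columns: hom-major, het, hom-minor in the
# printed row order; cohort sizes 38 (e-Dec) and 94 (on-site).  SNPs with
# source=mono were reported monomorphic (no minor allele observed).
rsid	maj	min	edec_hom_maj	edec_het	edec_hom_min	onsite_hom_maj	onsite_het	onsite_hom_min	source
rs28399433	T	G	30	7	1	32	59	3	table4
rs28399434	G	A	38	0	0	88	6	0	table4
rs8192720	C	T	37	1	0	94	0	0	table4
rs1137115	G	A	27	10	1	69	23	2	table4
rs2431413	T	C	38	0	0	69	22	3	table4
rs5031017	G	T	19	13	6	43	35	16	table4
rs1801272	A	T	38	0	0	94	0	0	mono
rs199916117	T	C	38	0	0	94	0	0	mono
rs148166815	A	G	38	0	0	94	0	0	mono
rs1809810	T	A	38	0	0	94	0	0	mono
rs143731390	T	A	38	0	0	94	0	0	mono
rs5031016	A	G	38	0	0	94	0	0	mono
rs6413474	T	C	38	0	0	94	0	0	mono
rs28399468	C	A	38	0	0	94	0	0	mono
rs10189159	T	C	32	5	1	44	45	5	table5
rs985919	T	G	21	14	3	29	54	11	table5
rs10865246	A	C	21	15	2	38	42	14	table5
rs1882296	A	G	26	11	1	45	43	6	table5
rs1800955	T	C	19	17	2	43	37	14	table5
rs6311	G	A	19	14	5	35	46	13	table5
rs6313	C	T	22	14	2	77	9	8	table5
rs12914385	C	T	23	12	3	49	40	5	table5
rs1317286	A	G	28	9	1	49	40	5	table5
rs6495307	C	T	29	7	2	53	37	4	table5
rs615470	T	C	31	6	1	57	33	4	table5
rs16969968	G	A	25	11	2	53	35	6	table5
rs17408276	T	C	31	6	1	53	39	2	table5
rs951266	C	T	36	2	0	51	38	5	table5
rs680244	G	A	27	10	1	52	37	5	table5
rs17486278	A	C	24	11	3	46	43	5	table5
rs4105144	T	C	26	10	2	62	29	3	table5
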