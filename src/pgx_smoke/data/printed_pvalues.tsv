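# Published per-SNP comparison p-values (genotype-level and allele-level
# columns of the frequency tables), transcribed verbatim; "NS" = reported
# non-significant without a number.  p_collapsed holds the separately
# reported major-hom vs heterozygote 2x2 p for SNPs lacking minor-allele
# homozygotes.
rsid	p_genotype	p_allele	p_collapsed
rs28399433	<0.0001	0.0003	.
rs28399434	NS	NS	0.181
rs8192720	NS	NS	0.287
rs1137115	0.768	NS	.
rs2431413	NS	NS	.
rs5031017	0.700	NS	.
rs10189159	0.0004	0.0009	.
rs985919	0.0333	0.0437	.
rs10865246	0.0621	0.0783	.
rs1882296	0.0348	0.0589	.
rs1800955	0.2936	<0.0001	.
rs6311	0.3103	0.3750	.
rs6313	0.0772	0.0594	.
rs12914385	0.6203	0.7380	.
rs1317286	0.0311	0.1390	.
rs6495307	0.0903	0.1240	.
rs615470	0.0355	0.0499	.
rs16969968	0.3700	0.4510	.
rs17408276	0.0161	0.5280	.
rs951266	<0.0001	<0.0001	.
rs680244	0.1006	0.1430	.
rs17486278	0.3213	0.6000	.
rs4105144	0.9709	0.9701	.
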