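# Synthetic placeholder weights for the 12-SNP heart-failure genetic risk
# score (snp, effect_allele, beta = ln odds ratio per allele).  These are NOT
# published effect sizes; supply the study's own weight table for real use.
snp	effect_allele	beta
rs_syn_001	A	0.075
rs_syn_002	G	0.055
rs_syn_003	T	0.120
rs_syn_004	C	0.048
rs_syn_005	A	0.095
rs_syn_006	G	0.060
rs_syn_007	T	0.150
rs_syn_008	C	0.042
rs_syn_009	A	0.088
rs_syn_010	G	0.070
rs_syn_011	T	0.058
rs_syn_012	C	0.105
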