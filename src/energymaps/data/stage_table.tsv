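stage	min_pcd	max_pcd	index
early_fetal	56	112	0
mid_fetal	112	168	1
late_fetal	168	266	2
infancy	266	813	3
early_childhood	813	2456	4
late_childhood	2456	4646	5
adolescence	4646	7566	6
adulthood	7566	16000	7
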