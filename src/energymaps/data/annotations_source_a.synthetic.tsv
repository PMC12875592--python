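pathway_id	pathway_name	gene
GO:0006096	Glycolytic process	PFKFB2
GO:0006096	Glycolytic process	GPI
GO:0006096	Glycolytic process	PFKL
GO:0006096	Glycolytic process	PFKM
GO:0006096	Glycolytic process	PFKP
GO:0006096	Glycolytic process	ALDOA
GO:0006096	Glycolytic process	ALDOC
GO:0006096	Glycolytic process	TPI1
GO:0006096	Glycolytic process	GAPDH
GO:0006096	Glycolytic process	PGK1
GO:0006096	Glycolytic process	PGAM1
GO:0006096	Glycolytic process	ENO1
GO:0006096	Glycolytic process	ENO2
GO:0006096	Glycolytic process	PKM
GO:0006096	Glycolytic process	BPGM
GO:0006096	Glycolytic process	HK1
GO:0006096	Glycolytic process	HK2
GO:0006096	Glycolytic process	HK3
GO:0006096	Glycolytic process	HKDC1
GO:0006096	Glycolytic process	GALM
GO:0006098	Pentose-phosphate shunt	PGD
GO:0006098	Pentose-phosphate shunt	RPIA
GO:0006098	Pentose-phosphate shunt	RPEL1
GO:0006098	Pentose-phosphate shunt	RBKS
GO:0006098	Pentose-phosphate shunt	PRPS1
GO:0006098	Pentose-phosphate shunt	PRPS2
GO:0006098	Pentose-phosphate shunt	TKT
GO:0006098	Pentose-phosphate shunt	TALDO1
GO:0006098	Pentose-phosphate shunt	HK1
GO:0006098	Pentose-phosphate shunt	HK2
GO:0006098	Pentose-phosphate shunt	HK3
GO:0006098	Pentose-phosphate shunt	G6PD
GO:0006098	Pentose-phosphate shunt	PGLS
GO:0006099	Tricarboxylic acid cycle	CS
GO:0006099	Tricarboxylic acid cycle	ACO2
GO:0006099	Tricarboxylic acid cycle	IDH3A
GO:0006099	Tricarboxylic acid cycle	IDH3B
GO:0006099	Tricarboxylic acid cycle	IDH3G
GO:0006099	Tricarboxylic acid cycle	OGDH
GO:0006099	Tricarboxylic acid cycle	SUCLA2
GO:0006099	Tricarboxylic acid cycle	SUCLG1
GO:0006099	Tricarboxylic acid cycle	FH
GO:0006099	Tricarboxylic acid cycle	MDH1
GO:0006099	Tricarboxylic acid cycle	MDH2
GO:0006099	Tricarboxylic acid cycle	SDHA
GO:0006099	Tricarboxylic acid cycle	SDHB
GO:0006099	Tricarboxylic acid cycle	SDHC
GO:0006099	Tricarboxylic acid cycle	IDH2
GO:0006119	Oxidative phosphorylation	SDHA
GO:0006119	Oxidative phosphorylation	SDHB
GO:0006119	Oxidative phosphorylation	SDHC
GO:0006119	Oxidative phosphorylation	NDUFA1
GO:0006119	Oxidative phosphorylation	NDUFA2
GO:0006119	Oxidative phosphorylation	NDUFA3
GO:0006119	Oxidative phosphorylation	NDUFA5
GO:0006119	Oxidative phosphorylation	NDUFA6
GO:0006119	Oxidative phosphorylation	NDUFA8
GO:0006119	Oxidative phosphorylation	NDUFA9
GO:0006119	Oxidative phosphorylation	NDUFA10
GO:0006119	Oxidative phosphorylation	NDUFB1
GO:0006119	Oxidative phosphorylation	NDUFB2
GO:0006119	Oxidative phosphorylation	NDUFB3
GO:0006119	Oxidative phosphorylation	NDUFB5
GO:0006119	Oxidative phosphorylation	NDUFB6
GO:0006119	Oxidative phosphorylation	NDUFB8
GO:0006119	Oxidative phosphorylation	NDUFB10
GO:0006119	Oxidative phosphorylation	NDUFS1
GO:0006119	Oxidative phosphorylation	NDUFS2
GO:0006119	Oxidative phosphorylation	NDUFS3
GO:0006119	Oxidative phosphorylation	NDUFS4
GO:0006119	Oxidative phosphorylation	NDUFS7
GO:0006119	Oxidative phosphorylation	NDUFS8
GO:0006119	Oxidative phosphorylation	NDUFV1
GO:0006119	Oxidative phosphorylation	NDUFV2
GO:0006119	Oxidative phosphorylation	UQCRC1
GO:0006119	Oxidative phosphorylation	UQCRC2
GO:0006119	Oxidative phosphorylation	UQCRB
GO:0006119	Oxidative phosphorylation	UQCRH
GO:0006119	Oxidative phosphorylation	CYC1
GO:0006119	Oxidative phosphorylation	COX4I1
GO:0006119	Oxidative phosphorylation	COX5A
GO:0006119	Oxidative phosphorylation	COX5B
GO:0006119	Oxidative phosphorylation	COX6B1
GO:0006119	Oxidative phosphorylation	COX6C
GO:0006119	Oxidative phosphorylation	COX7A2
GO:0006119	Oxidative phosphorylation	COX7B
GO:0006119	Oxidative phosphorylation	COX8A
GO:0006119	Oxidative phosphorylation	ATP5F1A
GO:0006119	Oxidative phosphorylation	ATP5F1B
GO:0006119	Oxidative phosphorylation	ATP5F1C
GO:0006119	Oxidative phosphorylation	ATP5MC1
GO:0006119	Oxidative phosphorylation	ATP5PB
GO:0006119	Oxidative phosphorylation	ATP5PD
GO:0006119	Oxidative phosphorylation	NDUFAB1
GO:0006119	Oxidative phosphorylation	COX11
GO:0006089	Lactate metabolic process	PFKFB2
GO:0006089	Lactate metabolic process	LDHA
GO:0006089	Lactate metabolic process	LDHB
GO:0006089	Lactate metabolic process	LDHD
GO:0006089	Lactate metabolic process	SLC16A1
GO:0006089	Lactate metabolic process	SLC16A3
GO:0006089	Lactate metabolic process	SLC16A7
GO:0006089	Lactate metabolic process	SLC16A8
GO:0006089	Lactate metabolic process	MIR210
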