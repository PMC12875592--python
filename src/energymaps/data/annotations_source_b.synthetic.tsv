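pathway_id	pathway_name	gene
R-HSA-70171	Glycolytic process	PFKFB2
R-HSA-70171	Glycolytic process	GPI
R-HSA-70171	Glycolytic process	PFKL
R-HSA-70171	Glycolytic process	PFKM
R-HSA-70171	Glycolytic process	PFKP
R-HSA-70171	Glycolytic process	ALDOA
R-HSA-70171	Glycolytic process	ALDOC
R-HSA-70171	Glycolytic process	TPI1
R-HSA-70171	Glycolytic process	GAPDH
R-HSA-70171	Glycolytic process	PGK1
R-HSA-70171	Glycolytic process	PGAM1
R-HSA-70171	Glycolytic process	ENO1
R-HSA-70171	Glycolytic process	ENO2
R-HSA-70171	Glycolytic process	PKM
R-HSA-70171	Glycolytic process	BPGM
R-HSA-70171	Glycolytic process	HK1
R-HSA-70171	Glycolytic process	HK2
R-HSA-70171	Glycolytic process	HK3
R-HSA-70171	Glycolytic process	ADPGK
R-HSA-70171	Glycolytic process	PGM1
R-HSA-71336	Pentose-phosphate shunt	PGD
R-HSA-71336	Pentose-phosphate shunt	RPIA
R-HSA-71336	Pentose-phosphate shunt	RPEL1
R-HSA-71336	Pentose-phosphate shunt	RBKS
R-HSA-71336	Pentose-phosphate shunt	PRPS1
R-HSA-71336	Pentose-phosphate shunt	PRPS2
R-HSA-71336	Pentose-phosphate shunt	TKT
R-HSA-71336	Pentose-phosphate shunt	TALDO1
R-HSA-71336	Pentose-phosphate shunt	HK1
R-HSA-71336	Pentose-phosphate shunt	HK2
R-HSA-71336	Pentose-phosphate shunt	HK3
R-HSA-71336	Pentose-phosphate shunt	TKTL1
R-HSA-71336	Pentose-phosphate shunt	DERA
R-HSA-71403	Tricarboxylic acid cycle	CS
R-HSA-71403	Tricarboxylic acid cycle	ACO2
R-HSA-71403	Tricarboxylic acid cycle	IDH3A
R-HSA-71403	Tricarboxylic acid cycle	IDH3B
R-HSA-71403	Tricarboxylic acid cycle	IDH3G
R-HSA-71403	Tricarboxylic acid cycle	OGDH
R-HSA-71403	Tricarboxylic acid cycle	SUCLA2
R-HSA-71403	Tricarboxylic acid cycle	SUCLG1
R-HSA-71403	Tricarboxylic acid cycle	FH
R-HSA-71403	Tricarboxylic acid cycle	MDH1
R-HSA-71403	Tricarboxylic acid cycle	MDH2
R-HSA-71403	Tricarboxylic acid cycle	SDHA
R-HSA-71403	Tricarboxylic acid cycle	SDHB
R-HSA-71403	Tricarboxylic acid cycle	SDHC
R-HSA-71403	Tricarboxylic acid cycle	NNT
R-HSA-1428517	Oxidative phosphorylation	SDHA
R-HSA-1428517	Oxidative phosphorylation	SDHB
R-HSA-1428517	Oxidative phosphorylation	SDHC
R-HSA-1428517	Oxidative phosphorylation	NDUFA1
R-HSA-1428517	Oxidative phosphorylation	NDUFA2
R-HSA-1428517	Oxidative phosphorylation	NDUFA3
R-HSA-1428517	Oxidative phosphorylation	NDUFA5
R-HSA-1428517	Oxidative phosphorylation	NDUFA6
R-HSA-1428517	Oxidative phosphorylation	NDUFA8
R-HSA-1428517	Oxidative phosphorylation	NDUFA9
R-HSA-1428517	Oxidative phosphorylation	NDUFA10
R-HSA-1428517	Oxidative phosphorylation	NDUFB1
R-HSA-1428517	Oxidative phosphorylation	NDUFB2
R-HSA-1428517	Oxidative phosphorylation	NDUFB3
R-HSA-1428517	Oxidative phosphorylation	NDUFB5
R-HSA-1428517	Oxidative phosphorylation	NDUFB6
R-HSA-1428517	Oxidative phosphorylation	NDUFB8
R-HSA-1428517	Oxidative phosphorylation	NDUFB10
R-HSA-1428517	Oxidative phosphorylation	NDUFS1
R-HSA-1428517	Oxidative phosphorylation	NDUFS2
R-HSA-1428517	Oxidative phosphorylation	NDUFS3
R-HSA-1428517	Oxidative phosphorylation	NDUFS4
R-HSA-1428517	Oxidative phosphorylation	NDUFS7
R-HSA-1428517	Oxidative phosphorylation	NDUFS8
R-HSA-1428517	Oxidative phosphorylation	NDUFV1
R-HSA-1428517	Oxidative phosphorylation	NDUFV2
R-HSA-1428517	Oxidative phosphorylation	UQCRC1
R-HSA-1428517	Oxidative phosphorylation	UQCRC2
R-HSA-1428517	Oxidative phosphorylation	UQCRB
R-HSA-1428517	Oxidative phosphorylation	UQCRH
R-HSA-1428517	Oxidative phosphorylation	CYC1
R-HSA-1428517	Oxidative phosphorylation	COX4I1
R-HSA-1428517	Oxidative phosphorylation	COX5A
R-HSA-1428517	Oxidative phosphorylation	COX5B
R-HSA-1428517	Oxidative phosphorylation	COX6B1
R-HSA-1428517	Oxidative phosphorylation	COX6C
R-HSA-1428517	Oxidative phosphorylation	COX7A2
R-HSA-1428517	Oxidative phosphorylation	COX7B
R-HSA-1428517	Oxidative phosphorylation	COX8A
R-HSA-1428517	Oxidative phosphorylation	ATP5F1A
R-HSA-1428517	Oxidative phosphorylation	ATP5F1B
R-HSA-1428517	Oxidative phosphorylation	ATP5F1C
R-HSA-1428517	Oxidative phosphorylation	ATP5MC1
R-HSA-1428517	Oxidative phosphorylation	ATP5PB
R-HSA-1428517	Oxidative phosphorylation	ATP5PD
R-HSA-1428517	Oxidative phosphorylation	SURF1
R-HSA-1428517	Oxidative phosphorylation	COA3
R-HSA-70268	Lactate metabolic process	PFKFB2
R-HSA-70268	Lactate metabolic process	LDHA
R-HSA-70268	Lactate metabolic process	LDHB
R-HSA-70268	Lactate metabolic process	LDHD
R-HSA-70268	Lactate metabolic process	SLC16A1
R-HSA-70268	Lactate metabolic process	SLC16A3
R-HSA-70268	Lactate metabolic process	SLC16A7
R-HSA-70268	Lactate metabolic process	SLC16A8
R-HSA-70268	Lactate metabolic process	EMB
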