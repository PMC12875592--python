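pathway	gene	source_A_id	source_B_id
glycolysis	PFKFB2	GO:0006096	R-HSA-70171
glycolysis	GPI	GO:0006096	R-HSA-70171
glycolysis	PFKL	GO:0006096	R-HSA-70171
glycolysis	PFKM	GO:0006096	R-HSA-70171
glycolysis	PFKP	GO:0006096	R-HSA-70171
glycolysis	ALDOA	GO:0006096	R-HSA-70171
glycolysis	ALDOC	GO:0006096	R-HSA-70171
glycolysis	TPI1	GO:0006096	R-HSA-70171
glycolysis	GAPDH	GO:0006096	R-HSA-70171
glycolysis	PGK1	GO:0006096	R-HSA-70171
glycolysis	PGAM1	GO:0006096	R-HSA-70171
glycolysis	ENO1	GO:0006096	R-HSA-70171
glycolysis	ENO2	GO:0006096	R-HSA-70171
glycolysis	PKM	GO:0006096	R-HSA-70171
glycolysis	BPGM	GO:0006096	R-HSA-70171
ppp	PGD	GO:0006098	R-HSA-71336
ppp	RPIA	GO:0006098	R-HSA-71336
ppp	RPEL1	GO:0006098	R-HSA-71336
ppp	RBKS	GO:0006098	R-HSA-71336
ppp	PRPS1	GO:0006098	R-HSA-71336
ppp	PRPS2	GO:0006098	R-HSA-71336
ppp	TKT	GO:0006098	R-HSA-71336
ppp	TALDO1	GO:0006098	R-HSA-71336
tca	CS	GO:0006099	R-HSA-71403
tca	ACO2	GO:0006099	R-HSA-71403
tca	IDH3A	GO:0006099	R-HSA-71403
tca	IDH3B	GO:0006099	R-HSA-71403
tca	IDH3G	GO:0006099	R-HSA-71403
tca	OGDH	GO:0006099	R-HSA-71403
tca	SUCLA2	GO:0006099	R-HSA-71403
tca	SUCLG1	GO:0006099	R-HSA-71403
tca	FH	GO:0006099	R-HSA-71403
tca	MDH1	GO:0006099	R-HSA-71403
tca	MDH2	GO:0006099	R-HSA-71403
tca	SDHA	GO:0006099	R-HSA-71403
tca	SDHB	GO:0006099	R-HSA-71403
tca	SDHC	GO:0006099	R-HSA-71403
oxphos	SDHA	GO:0006119	R-HSA-1428517
oxphos	SDHB	GO:0006119	R-HSA-1428517
oxphos	SDHC	GO:0006119	R-HSA-1428517
oxphos	NDUFA1	GO:0006119	R-HSA-1428517
oxphos	NDUFA2	GO:0006119	R-HSA-1428517
oxphos	NDUFA3	GO:0006119	R-HSA-1428517
oxphos	NDUFA5	GO:0006119	R-HSA-1428517
oxphos	NDUFA6	GO:0006119	R-HSA-1428517
oxphos	NDUFA8	GO:0006119	R-HSA-1428517
oxphos	NDUFA9	GO:0006119	R-HSA-1428517
oxphos	NDUFA10	GO:0006119	R-HSA-1428517
oxphos	NDUFB1	GO:0006119	R-HSA-1428517
oxphos	NDUFB2	GO:0006119	R-HSA-1428517
oxphos	NDUFB3	GO:0006119	R-HSA-1428517
oxphos	NDUFB5	GO:0006119	R-HSA-1428517
oxphos	NDUFB6	GO:0006119	R-HSA-1428517
oxphos	NDUFB8	GO:0006119	R-HSA-1428517
oxphos	NDUFB10	GO:0006119	R-HSA-1428517
oxphos	NDUFS1	GO:0006119	R-HSA-1428517
oxphos	NDUFS2	GO:0006119	R-HSA-1428517
oxphos	NDUFS3	GO:0006119	R-HSA-1428517
oxphos	NDUFS4	GO:0006119	R-HSA-1428517
oxphos	NDUFS7	GO:0006119	R-HSA-1428517
oxphos	NDUFS8	GO:0006119	R-HSA-1428517
oxphos	NDUFV1	GO:0006119	R-HSA-1428517
oxphos	NDUFV2	GO:0006119	R-HSA-1428517
oxphos	UQCRC1	GO:0006119	R-HSA-1428517
oxphos	UQCRC2	GO:0006119	R-HSA-1428517
oxphos	UQCRB	GO:0006119	R-HSA-1428517
oxphos	UQCRH	GO:0006119	R-HSA-1428517
oxphos	CYC1	GO:0006119	R-HSA-1428517
oxphos	COX4I1	GO:0006119	R-HSA-1428517
oxphos	COX5A	GO:0006119	R-HSA-1428517
oxphos	COX5B	GO:0006119	R-HSA-1428517
oxphos	COX6B1	GO:0006119	R-HSA-1428517
oxphos	COX6C	GO:0006119	R-HSA-1428517
oxphos	COX7A2	GO:0006119	R-HSA-1428517
oxphos	COX7B	GO:0006119	R-HSA-1428517
oxphos	COX8A	GO:0006119	R-HSA-1428517
oxphos	ATP5F1A	GO:0006119	R-HSA-1428517
oxphos	ATP5F1B	GO:0006119	R-HSA-1428517
oxphos	ATP5F1C	GO:0006119	R-HSA-1428517
oxphos	ATP5MC1	GO:0006119	R-HSA-1428517
oxphos	ATP5PB	GO:0006119	R-HSA-1428517
oxphos	ATP5PD	GO:0006119	R-HSA-1428517
lactate	PFKFB2	GO:0006089	R-HSA-70268
lactate	LDHA	GO:0006089	R-HSA-70268
lactate	LDHB	GO:0006089	R-HSA-70268
lactate	LDHD	GO:0006089	R-HSA-70268
lactate	SLC16A1	GO:0006089	R-HSA-70268
lactate	SLC16A3	GO:0006089	R-HSA-70268
lactate	SLC16A7	GO:0006089	R-HSA-70268
lactate	SLC16A8	GO:0006089	R-HSA-70268
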