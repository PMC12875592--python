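pathway	gene	source_A_id	source_B_id
ketone_body	BDH1	GO:0046952	R-HSA-77108
ketone_body	BDH2	GO:0046952	R-HSA-77108
ketone_body	OXCT1	GO:0046952	R-HSA-77108
ketone_body	ACAT1	GO:0046952	R-HSA-77108
ketone_body	SLC16A6	GO:0046952	R-HSA-77108
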