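stromal_signature	Synthetic stand-in stromal signature (fibroblast/ECM markers); supply real ESTIMATE signatures as GMT for production use	COL1A1	COL1A2	COL3A1	COL5A1	COL6A3	FAP	THY1	PDGFRA	PDGFRB	ACTA2	TAGLN	FN1	LUM	DCN	POSTN	SPARC	MMP2	VCAN	FBLN1	THBS2
immune_signature	Synthetic stand-in immune signature (leukocyte markers); supply real ESTIMATE signatures as GMT for production use	PTPRC	CD3D	CD3E	CD2	CD8A	CD19	MS4A1	CD79A	LCK	ZAP70	IL7R	CCL5	CXCR4	GZMB	PRF1	NKG7	KLRD1	FCGR3A	ITGAM	CSF1R
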