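immune_checkpoint	Immune checkpoint genes: ligands, receptors and key pathway molecules (curated stand-in list)	ADORA2A	BTLA	BTN2A1	BTN2A2	BTN3A1	BTN3A2	BTNL2	CD160	CD200	CD200R1	CD226	CD244	CD27	CD274	CD276	CD28	CD40	CD40LG	CD44	CD47	CD48	CD70	CD80	CD86	CEACAM1	CTLA4	HAVCR2	HHLA2	ICOS	ICOSLG	IDO1	IDO2	KIR2DL1	KIR2DL3	KIR3DL1	LAG3	LAIR1	LAIR2	LGALS9	NECTIN2	NRP1	PDCD1	PDCD1LG2	PVR	SIRPA	TIGIT	TMIGD2	TNFRSF14	TNFRSF18	TNFRSF25	TNFRSF4	TNFRSF8	TNFRSF9	TNFSF14	TNFSF15	TNFSF18	TNFSF4	TNFSF9	VSIR	VTCN1
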