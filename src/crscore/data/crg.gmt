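clock_control	Clock control genes: stabilizing/output-loop regulators of the core oscillator (curated stand-in list)	HLF	KLF10	FBXL3	FBXL21	TEF	RORA	RORB	RORC	NR1D1	NR1D2	DBP	NFIL3	SERPINE1
core_clock	Core clock genes: the primary transcription-translation feedback loop and its kinases/modifiers (curated stand-in list)	CLOCK	ARNTL	ARNTL2	NPAS2	PER1	PER2	PER3	CRY1	CRY2	CSNK1D	CSNK1E	CSNK2A1	CSNK2B	TIMELESS	TIPIN	METTL3	BHLHE40	BHLHE41	HCRTR2	MTNR1A	MTNR1B	NPFF	GSK3B	AUTS2	REV1	VIPR2	BTRC	FBXW11	PRKAA1	PRKAA2	NONO	SFPQ	RAI1	CIPC	CREB1
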