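name	pattern	family
oct_pax19	H[ST]V[ST][DN][IL]LG	Pax1/9
oct_pax258	Y[TS]IX2ILG	Pax2/5/8
poxn_junction	KPKQVAT	PoxNeuro
poxn_postprd	[VI]PGLSYP[KR][IL]V	PoxNeuro
mdkl_linker	MDKL	Pax4/6
beta_motif1	YDY[NS]LPDRGL	Paxβ
beta_motif2	PLDLS	Paxβ
beta_motif3	Y[ED][RK]N[LVM]L[LI]FGD[SNQ]E[IVL]EI[MI]SVGKX[KR]W[IV][VI]RNEX[DE]L	Paxβ
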