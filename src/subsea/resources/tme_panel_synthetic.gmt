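cytolytic_activity	immune; synthetic stand-in marker genes, replace with a published signature	GZMA	PRF1	GZMB	GZMH	GNLY
lymphocytes	immune; synthetic stand-in marker genes, replace with a published signature	CD2	CD3D	CD3E	CD247	IL7R	LCK	CD52
hypoxia	vascularization; synthetic stand-in marker genes, replace with a published signature	VEGFA	SLC2A1	CA9	LDHA	PGK1	ADM
lymphangiogenesis	vascularization; synthetic stand-in marker genes, replace with a published signature	LYVE1	PDPN	PROX1	FLT4	CCL21
stromal	stromal; synthetic stand-in marker genes, replace with a published signature	COL1A1	COL1A2	COL3A1	FAP	ACTA2	THY1	DCN
glycolysis	metabolism; synthetic stand-in marker genes, replace with a published signature	HK2	PFKM	PKM	ALDOA	ENO1	GAPDH
lipid_metabolism	metabolism; synthetic stand-in marker genes, replace with a published signature	FASN	SCD	ACACA	CPT1A	PLIN2
pentose_phosphate_pathway	metabolism; synthetic stand-in marker genes, replace with a published signature	G6PD	PGD	TKT	TALDO1	RPIA
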