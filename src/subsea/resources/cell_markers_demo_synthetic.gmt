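B_cells	immune; synthetic demo marker set	MS4A1	CD79A	CD79B	CD19	BANK1
CD4_T_cells	immune; synthetic demo marker set	CD4	IL7R	CD3D	CD3E	TRAC
CD8_T_cells	immune; synthetic demo marker set	CD8A	CD8B	GZMK	CD3G	TRGC2
NK_cells	immune; synthetic demo marker set	NKG7	GNLY	KLRD1	NCR1	KLRF1
Macrophages	immune; synthetic demo marker set	CD68	CD163	CSF1R	MRC1	MSR1
Dendritic_cells	immune; synthetic demo marker set	CD1C	FCER1A	CLEC9A	ITGAX	IRF8
Neutrophils	immune; synthetic demo marker set	FCGR3B	CSF3R	S100A8	S100A9	FPR1
Fibroblasts	stromal; synthetic demo marker set	COL1A1	DCN	FAP	PDGFRA	LUM
Endothelial_cells	stromal; synthetic demo marker set	PECAM1	VWF	CDH5	CLDN5	KDR
Adipocytes	stromal; synthetic demo marker set	ADIPOQ	LEP	PLIN1	CFD	FABP4
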