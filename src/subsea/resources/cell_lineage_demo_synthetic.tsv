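cell	lineage
B_cells	immune
CD4_T_cells	immune
CD8_T_cells	immune
NK_cells	immune
Macrophages	immune
Dendritic_cells	immune
Neutrophils	immune
Fibroblasts	stromal
Endothelial_cells	stromal
Adipocytes	stromal
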