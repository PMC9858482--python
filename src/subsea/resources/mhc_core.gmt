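mhc_core	core MHC class I antigen-presentation genes	HLA-A	HLA-B	HLA-C	TAP1	TAP2	NLRC5	PSMB9	PSMB8	B2M
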