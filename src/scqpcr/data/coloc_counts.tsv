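pair_label	assay	reference	target	n_reference	n_double	pct_printed
MCH_Pdyn	FISH	Pmch	Pdyn	47	0	0.0
MCH_Cartpt	FISH	Pmch	Cartpt	190	99	52.1
MCH_Nucb2	FISH	Pmch	Nucb2	77	57	74.0
MCH_Penk	FISH	Pmch	Penk	85	23	27.1
HcrtOx_Pdyn	FISH	Hcrt	Pdyn	125	123	98.4
HcrtOx_Cartpt	FISH	Hcrt	Cartpt	154	13	8.4
HcrtOx_Nucb2	FISH	Hcrt	Nucb2	90	76	84.4
HcrtOx_Penk	FISH	Hcrt	Penk	169	53	31.4
MCH_Slc17a6	FISH	Pmch	Slc17a6	51	48	94.1
MCH_Slc32a1	FISH	Pmch	Slc32a1	63	2	3.2
MCH_Gad1	FISH	Pmch	Gad1	224	189	84.4
HcrtOx_Slc17a6	FISH	Hcrt	Slc17a6	45	45	100.0
HcrtOx_Slc32a1	FISH	Hcrt	Slc32a1	170	5	2.9
HcrtOx_Gad1	FISH	Hcrt	Gad1	237	73	30.8
MCH_CART	IHC	MCH	CART	126	60	47.6
MCH_NUCB2	IHC	MCH	NUCB2	134	134	100.0
HcrtOx_CART	IHC	OxA	CART	115	1	0.8
HcrtOx_NUCB2	IHC	OxA	NUCB2	120	119	99.2
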