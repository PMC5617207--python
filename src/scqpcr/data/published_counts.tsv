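symbol	k_mch	n_mch	k_hcrt	n_hcrt	prop_diff	p_adj_printed	sig
Pdyn	1	89	69	69	99.0	5.12E-43	1
Lhx9	3	89	69	69	97.0	2.18E-40	1
Hcrt	5	89	69	69	94.0	3.93E-38	1
Pmch	89	89	6	69	91.0	1.59E-36	1
Igfbp3	20	89	69	69	78.0	6.90E-26	1
Th	14	89	60	69	71.0	1.84E-19	1
Nptx2	29	89	69	69	67.0	7.82E-21	1
Nkx2.1	54	89	0	69	61.0	9.11E-18	1
Nnat	39	89	68	69	55.0	1.78E-14	1
Penk	26	89	53	69	48.0	1.43E-08	1
Rbfox3	86	89	37	69	43.0	1.81E-10	1
Gad1	87	89	39	69	41.0	1.87E-10	1
Slc17a8	8	89	33	69	39.0	1.30E-07	1
Pnoc	31	89	0	69	35.0	5.08E-09	1
Nucb2	68	89	69	69	24.0	6.23E-06	1
Cartpt	59	89	29	69	24.0	9.39E-03	1
Sst	0	89	14	69	20.0	1.21E-05	1
Gal	49	89	49	69	16.0	NA	0
Calb1	76	89	69	69	15.0	1.70E-03	1
Calb2	80	89	68	69	9.0	NA	0
Ghsr	2	89	7	69	8.0	NA	0
Mc4r	27	89	16	69	7.0	NA	0
Slc18a1	0	89	4	69	6.0	NA	0
Pvalb	2	89	6	69	6.0	NA	0
Nts	16	89	8	69	6.0	NA	0
Tac1	6	89	8	69	5.0	NA	0
Gad2	19	89	11	69	5.0	NA	0
Tph1	0	89	2	69	3.0	NA	0
Slc17a6	87	89	69	69	2.0	NA	0
Ada	2	89	0	69	2.0	NA	0
Lepr	6	89	3	69	2.0	NA	0
Crh	16	89	11	69	2.0	NA	0
S100b	16	89	11	69	2.0	NA	0
Gfap	4	89	2	69	2.0	NA	0
Slc32a1	0	89	1	69	1.0	NA	0
Map2	88	89	69	69	1.0	NA	0
Tph2	1	89	0	69	1.0	NA	0
Trh	7	89	6	69	1.0	NA	0
Slc18a2	2	89	1	69	1.0	NA	0
Hprt	89	89	69	69	0.0	NA	0
Gapdh	89	89	69	69	0.0	NA	0
Slc17a7	0	89	0	69	0.0	NA	0
Hdc	0	89	0	69	0.0	NA	0
Tac2	0	89	0	69	0.0	NA	0
Tubb3	89	89	69	69	0.0	NA	0
Gls	89	89	69	69	0.0	NA	0
Chat	0	89	0	69	0.0	NA	0
Celf6	89	89	69	69	0.0	NA	0
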