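component	Hsa	Sce	Ddi	Ath	Tps	Ehu	Tva	Gin	Cme	Tbr	Ngr	Egr	Sin
Tom40	1	1	1	1	1	1	1	1	1	1	1	1	1
Tom22	1	1	1	1	1	1	1	0	1	1	1	1	1
Tom7	1	1	1	1	1	1	0	0	1	0	1	1	1
Tom70	1	1	1	0	1	0	0	0	0	0	0	0	0
Tom20	1	1	0	0	0	0	0	0	0	0	0	0	0
Sam50	1	1	1	1	1	1	1	1	1	1	1	1	1
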