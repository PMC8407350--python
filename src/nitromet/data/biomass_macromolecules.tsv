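molecule	percent_dry_weight	sd
RNA	2.4	0.04
DNA	1	ND
protein	46.7	4.7
carbohydrate	26.9	1.8
lipid	16.3	3.2
inorganic	5	ND
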