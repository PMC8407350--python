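amino_acid	umol_per_mg_dry_weight	sd
Ala	300.6	45.7
Arg	311.8	63.9
Asp	82.3	12.3
Glu	85	16.1
Gly	825.2	116.1
His	37.7	2.6
Ile	198.7	62.1
Leu	309.2	66.6
Lys	105.9	22.2
Met	194	22.8
Phe	224.3	107.9
Pro	641	227
Ser	297.5	62.6
Thr	277.2	70
Tyr	41.9	ND
Val	374	59.2
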