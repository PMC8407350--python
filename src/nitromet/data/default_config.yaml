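# Default run configuration for the N. moscoviensis core model.
etc:
  nxr_periplasmic_h: 2     # H+ released in the periplasm per NO2- oxidized
  complex_iii: 4           # charges per 2 e- (Q cycle, both directions)
  complex_i: 4             # charges per 2 e-
  complex_i_2m: 8          # charges per 2 e- (quinol -> ferredoxin)
  terminal_oxidase: 2      # bd-type charge separation per 2 e-
  h_per_atp: 4             # calibrated so the net nitrite ATP yield is 1.0
options:
  rgp_enabled: true
  hydrogenase_enabled: true
maintenance:
  gam: 535.0               # mmol ATP gDW-1 (recalibrated by the pipeline)
  ngam: 0.90               # mmol ATP gDW-1 h-1
operating_point: [8.5, 0.006]
measured_formate_growth: 0.004
isotope:
  p13: 0.0107
  tracer_fraction: 0.65
seeds:
  master: 20210817
output_dir: nitromet_out
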