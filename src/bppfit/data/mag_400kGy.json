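{
  "frequency_MHz": 25,
  "motions": [
    {"tau0_s": 6.25e-12, "ea_kJ_per_mol": 12.09, "dm2_G2": 0.039},
    {"tau0_s": 2.72e-14, "ea_kJ_per_mol": 19.09, "dm2_G2": 0.101},
    {"tau0_s": 2.07e-12, "ea_kJ_per_mol": 7.19, "dm2_G2": 0.004},
    {"tau0_s": 1.41e-12, "ea_kJ_per_mol": 1.85, "dm2_G2": 0.164}
  ]
}
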