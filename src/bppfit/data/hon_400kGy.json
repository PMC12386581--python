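{
  "frequency_MHz": 25,
  "motions": [
    {"tau0_s": 9.99e-11, "ea_kJ_per_mol": 8.28, "dm2_G2": 0.030},
    {"tau0_s": 1.10e-11, "ea_kJ_per_mol": 7.85, "dm2_G2": 0.058},
    {"tau0_s": 2.31e-12, "ea_kJ_per_mol": 6.07, "dm2_G2": 0.004}
  ]
}
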