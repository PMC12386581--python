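{
  "frequency_MHz": 25,
  "motions": [
    {"tau0_s": 9.99e-11, "ea_kJ_per_mol": 8.40, "dm2_G2": 0.024},
    {"tau0_s": 7.24e-12, "ea_kJ_per_mol": 8.49, "dm2_G2": 0.033}
  ]
}
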