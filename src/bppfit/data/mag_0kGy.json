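{
  "frequency_MHz": 25,
  "motions": [
    {"tau0_s": 4.45e-12, "ea_kJ_per_mol": 12.77, "dm2_G2": 0.036},
    {"tau0_s": 2.12e-14, "ea_kJ_per_mol": 19.55, "dm2_G2": 0.110},
    {"tau0_s": 5.83e-14, "ea_kJ_per_mol": 9.66, "dm2_G2": 0.003}
  ]
}
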