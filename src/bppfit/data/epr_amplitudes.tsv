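compound	dose_kGy	amplitude_initial	amplitude_3m
HON	0	5.7	0.4
HON	25	9.4	3.8
HON	100	29.8	5.8
HON	400	71.2	15.0
MAG	0	3.2	2.3
MAG	25	9.5	2.7
MAG	100	13.7	3.4
MAG	400	28.8	6.5
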