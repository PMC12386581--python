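compound	dose_kGy	mean_percent	sd_percent	reference
HON	0	101.52	2.32	theoretical
HON	25	95.99	0.96	unirradiated
HON	100	97.65	1.44	unirradiated
HON	400	95.78	0.95	unirradiated
MAG	0	100.68	1.54	theoretical
MAG	25	101.37	0.97	unirradiated
MAG	100	98.40	1.22	unirradiated
MAG	400	95.13	0.97	unirradiated
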