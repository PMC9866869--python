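code_id	extremum	A	T	C	G	Fpi
1	min	0.05	0.07	0.2	0.68	0.245
2	min	0.05	0.12	0.66	0.17	0.430
21	min	0.05	0.06	0.68	0.21	0.203
1	max	0.84	0.05	0.05	0.06	9.01596
22	max	0.84	0.05	0.05	0.06	11.3414
23	max	0.84	0.05	0.05	0.06	11.4083
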