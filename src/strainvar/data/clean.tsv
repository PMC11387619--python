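maf	cor	ii	pp	np	dp
0.01	0.388	0.156	0.279	3.689	0.234
0.02	0.424	0.129	0.246	3.033	0.228
0.03	0.524	0.161	0.255	2.400	0.074
0.04	0.512	0.055	0.215	2.161	0.160
0.05	0.459	0.0497	0.186	2.009	0.144
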