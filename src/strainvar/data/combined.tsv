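maf	cor	ii	pp	np	dp
0.01	0.502	0.180	0.265	4.022	0.159
0.02	0.483	0.121	0.274	3.732	0.169
0.03	0.453	0.116	0.245	3.235	0.174
0.04	0.528	0.106	0.228	2.811	0.131
0.05	0.536	0.103	0.218	2.793	0.131
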