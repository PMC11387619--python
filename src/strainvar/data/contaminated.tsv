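maf	cor	ii	pp	np	dp
0.01	0.453	0.179	0.289	4.024	0.213
0.02	0.462	0.196	0.328	3.780	0.167
0.03	0.451	0.102	0.280	3.726	0.182
0.04	0.503	0.1301	0.274	3.719	0.151
0.05	0.513	0.118	0.233	3.450	0.145
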