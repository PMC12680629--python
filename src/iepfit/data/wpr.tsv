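# COVID-19 cumulative case fatality rates (percent), WHO Western Pacific Region, n=18
0.106
0.116
0.122
0.137
0.145
0.185
0.195
0.221
0.226
0.307
0.372
0.472
0.708
0.726
1.282
1.430
1.597
2.200
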