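# COVID-19 cumulative case fatality rates (percent), WHO South-East Asian Region, n=8
0.169
0.724
1.182
1.199
1.441
2.377
2.510
3.041
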