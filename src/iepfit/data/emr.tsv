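# COVID-19 cumulative case fatality rates (percent), WHO Eastern Mediterranean Region, n=21
0.134
0.220
0.220
0.386
0.808
0.883
1.029
1.146
1.159
1.205
1.269
1.278
1.922
1.939
2.551
3.534
4.812
4.979
5.508
7.885
18.075
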