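# COVID-19 cumulative case fatality rates (percent), WHO African Region, n=42
0.338
0.341
0.582
0.627
0.646
0.734
0.735
0.751
0.848
0.852
0.961
1.011
1.068
1.102
1.165
1.183
1.214
1.512
1.565
1.578
1.610
1.654
1.757
1.795
1.835
1.841
1.906
1.964
2.047
2.086
2.115
2.150
2.214
2.241
2.383
2.519
2.520
2.531
2.946
3.024
3.311
3.634
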