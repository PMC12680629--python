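# COVID-19 cumulative case fatality rates (percent), WHO Region of the Americas, n=35
0.470
0.566
0.657
0.696
0.735
0.761
0.765
0.826
0.972
1.060
1.090
1.131
1.165
1.209
1.288
1.299
1.361
1.533
1.592
1.603
1.705
1.770
1.857
1.868
2.096
2.216
2.241
2.292
2.307
2.345
2.507
2.713
3.371
4.380
4.901
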