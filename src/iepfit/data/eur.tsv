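# COVID-19 cumulative case fatality rates (percent), WHO European Region, n=50
0.206
0.257
0.261
0.261
0.267
0.318
0.331
0.371
0.378
0.397
0.431
0.455
0.482
0.484
0.513
0.532
0.591
0.596
0.680
0.697
0.701
0.703
0.709
0.716
0.716
0.730
0.733
0.737
0.756
0.872
0.909
0.925
0.927
1.057
1.079
1.134
1.165
1.237
1.269
1.435
1.740
1.835
1.948
1.953
1.992
2.001
2.215
2.854
2.955
4.057
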