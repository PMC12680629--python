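# COVID-19 cumulative case fatality rates (percent), OECD member countries, n=36
# Decimal-comma separators in the source were normalized to dot-decimal at packaging time.
0.105
0.137
0.196
0.221
0.257
0.261
0.261
0.267
0.318
0.371
0.378
0.431
0.455
0.482
0.532
0.596
0.680
0.697
0.701
0.716
0.733
0.737
0.756
0.761
0.872
0.909
0.922
0.927
1.090
1.131
1.134
1.165
1.835
2.215
2.242
4.380
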