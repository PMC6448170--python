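z_mm,normalized_intensity
-60.0,0.00000000
-58.0,0.00000000
-56.0,0.00000001
-54.0,0.00000039
-52.0,0.00001164
-50.0,0.00021332
-48.0,0.00244004
-46.0,0.01759384
-44.0,0.08124727
-42.0,0.24644253
-40.0,0.51140018
-38.0,0.77369599
-36.0,0.93293394
-34.0,0.99038453
-32.0,1.00000000
-30.0,0.99702744
-28.0,0.99210539
-26.0,0.98700198
-24.0,0.98188834
-22.0,0.97677434
-20.0,0.97166034
-18.0,0.96654634
-16.0,0.96143234
-14.0,0.95631833
-12.0,0.95120433
-10.0,0.94609033
-8.0,0.94097633
-6.0,0.93586233
-4.0,0.93074833
-2.0,0.92563432
0.0,0.92052032
2.0,0.91540632
4.0,0.91029232
6.0,0.90517832
8.0,0.90006431
10.0,0.89495031
12.0,0.88983631
14.0,0.88472231
16.0,0.87960831
18.0,0.87449431
20.0,0.86938030
22.0,0.86426630
24.0,0.85915229
26.0,0.85403798
28.0,0.84891492
30.0,0.84363860
32.0,0.83673469
34.0,0.81945522
36.0,0.76330959
38.0,0.62595505
40.0,0.40912014
42.0,0.19494708
44.0,0.06354985
46.0,0.01360706
48.0,0.00186591
50.0,0.00016129
52.0,0.00000870
54.0,0.00000029
56.0,0.00000001
58.0,0.00000000
60.0,0.00000000
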