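# Piecewise-linear HU -> mass density nodes (anchors: -1000 -> dry air, 0 -> water).
hu,density_g_cm3
-1500,0.00120479
-1000,0.00120479
0,1.000
100,1.100
2000,2.000
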