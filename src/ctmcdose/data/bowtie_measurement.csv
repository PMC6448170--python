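distance_cm,normalized_exposure
0,1.00000000
1,0.98840124
2,0.95483665
3,0.90268357
4,0.83666118
5,0.76188136
6,0.68307081
7,0.60411445
8,0.52790483
9,0.45639815
10,0.39077100
11,0.33160216
12,0.27903897
13,0.23293287
14,0.19294278
15,0.15861096
16,0.12941730
17,0.10481761
18,0.08427015
19,0.06725379
20,0.05327986
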