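hu_min,hu_max,hydrogen,oxygen,carbon,nitrogen,chlorine,calcium,phosphorus,magnesium
-1500,-938,0.000,0.237,0.000,0.765,0.000,0.000,0.000,0.000
-937,-104,0.103,0.749,0.105,0.031,0.003,0.000,0.002,0.002
-103,-70,0.116,0.187,0.693,0.001,0.001,0.000,0.000,0.000
-69,-40,0.113,0.308,0.566,0.009,0.001,0.000,0.000,0.000
-39,-9,0.110,0.409,0.460,0.015,0.002,0.000,0.001,0.000
-8,13,0.108,0.508,0.357,0.022,0.002,0.000,0.001,0.000
14,50,0.106,0.575,0.287,0.026,0.002,0.000,0.001,0.000
51,100,0.103,0.723,0.134,0.030,0.002,0.000,0.002,0.000
101,160,0.094,0.622,0.207,0.062,0.003,0.000,0.000,0.000
161,250,0.094,0.356,0.451,0.025,0.001,0.047,0.022,0.000
251,350,0.088,0.364,0.419,0.027,0.001,0.066,0.031,0.001
351,450,0.081,0.373,0.387,0.029,0.001,0.086,0.040,0.001
451,550,0.075,0.381,0.358,0.030,0.001,0.103,0.048,0.001
551,650,0.070,0.388,0.331,0.032,0.001,0.119,0.055,0.001
651,750,0.065,0.395,0.306,0.033,0.001,0.134,0.062,0.001
751,850,0.060,0.401,0.284,0.035,0.001,0.148,0.068,0.001
851,950,0.056,0.406,0.263,0.036,0.000,0.160,0.074,0.001
951,1050,0.052,0.411,0.244,0.037,0.000,0.172,0.079,0.002
1051,1150,0.048,0.416,0.226,0.038,0.000,0.182,0.084,0.002
1151,1250,0.045,0.420,0.209,0.039,0.000,0.192,0.088,0.002
1251,1350,0.042,0.425,0.194,0.040,0.000,0.202,0.092,0.002
1351,1450,0.039,0.428,0.179,0.041,0.000,0.210,0.096,0.002
1451,1550,0.036,0.432,0.166,0.041,0.000,0.219,0.100,0.002
1551,1800,0.034,0.436,0.153,0.042,0.000,0.226,0.104,0.002
1801,2000,0.028,0.443,0.124,0.044,0.000,0.243,0.111,0.002
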