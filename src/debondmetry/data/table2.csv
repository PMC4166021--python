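tooth,mean,sd,max,min,volume
1,0.0113,0.0074,0.0435,0.0001,0.076
2,0.0163,0.0148,0.073,1.4E-5,0.327
3,0.0326,0.0219,0.1394,2.4E-5,0.104
4,0.0142,0.0127,0.0975,4E-6,0.419
5,0.0387,0.0298,0.155,5.4E-5,0.033
6,0.0134,0.0123,0.0654,6.7E-5,0.002
7,0.0416,0.03,0.2071,0.0002,0.45
8,0.0263,0.0226,0.1266,3.7E-5,0.065
9,0.0213,0.0138,0.1027,0.0002,0.037
10,0.0305,0.0302,0.1677,1E-6,1.484
11,0.0149,0.0125,0.0662,2.4E-5,0.161
12,0.0282,0.0203,0.0857,8E-8,0.238
13,0.0246,0.0165,0.0843,0.0002,0.087
14,0.0223,0.0153,0.1083,4.4E-5,0.098
15,0.0076,0.0069,0.0375,1.4E-5,0.15
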