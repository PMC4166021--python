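tooth,mean,sd,max,min,volume
1,0.0099,0.0063,0.0325,1.5E-5,0.047
2,0.0688,0.0779,0.4251,0.0001,0.295
3,0.0952,0.0776,0.4061,2.7E-5,1.12
4,0.1349,0.0997,0.372,3.7E-5,0.678
5,0.238,0.1668,0.6986,0.0004,3.24
6,0.1492,0.1361,0.7606,4E-6,4.16
7,0.0662,0.0585,0.3323,0.0001,0.35
8,0.084,0.0584,0.3764,2.5E-5,1.52
9,0.1,0.0721,0.4727,0.0001,1.234
10,0.0168,0.013,0.0766,5.7E-5,0.271
11,0.0861,0.0646,0.2958,4.2E-5,1.256
12,0.0815,0.0649,0.3609,5.8E-5,0.988
13,0.065,0.0698,0.3296,9.5E-5,0.148
14,0.1518,0.1305,0.5752,0.0002,1.224
15,0.0087,0.007,0.0411,1.6E-5,0.108
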