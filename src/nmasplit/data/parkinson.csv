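study,treatment,mean,std.dev,sampleSize
1,A,-1.22,3.70,54
1,C,-1.53,4.28,95
2,A,-0.70,3.70,172
2,B,-2.40,3.40,173
3,A,-0.30,4.40,76
3,B,-2.60,4.30,71
3,D,-1.20,4.30,81
4,C,-0.24,3.00,128
4,D,-0.59,3.00,72
5,C,-0.73,3.00,80
5,D,-0.18,3.00,46
6,D,-2.20,2.31,137
6,E,-2.50,2.18,131
7,D,-1.80,2.48,154
7,E,-2.10,2.99,143
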