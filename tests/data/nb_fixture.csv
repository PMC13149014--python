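y,x1,x2
4,0.3047,-0.1849
0,-1.04,-0.6809
2,0.7505,1.2225
7,0.9406,-0.1545
1,-1.951,-0.4283
8,-1.3022,-0.3521
3,0.1278,0.5323
1,-0.3162,0.3654
4,-0.0168,0.4127
3,-0.853,0.4308
1,0.8794,2.1416
2,0.7778,-0.4064
5,0.066,-0.5122
12,1.1272,-0.8138
4,0.4675,0.616
4,-0.8593,1.129
3,0.3688,-0.1139
3,-0.9589,-0.8402
8,0.8785,-0.8245
0,-0.0499,0.6506
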