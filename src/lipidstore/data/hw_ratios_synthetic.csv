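station,ratio
0.00,1.00
0.05,1.10
0.10,1.20
0.15,1.25
0.20,1.25
0.25,1.20
0.30,1.15
0.35,1.10
0.40,1.05
0.45,1.00
0.50,0.97
0.55,0.95
0.60,0.95
0.65,0.98
0.70,1.02
0.75,1.08
0.80,1.15
0.85,1.25
0.90,1.35
0.95,1.25
1.00,1.00
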