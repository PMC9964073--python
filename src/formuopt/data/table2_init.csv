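X1,X2,X3,Y2
1,0.1,1,20.00
1,0.1,1,27.50
1.5,0.2,0.5,42.70
0.5,0.2,0.5,5.00
1.5,0,0.5,1.70
1,0.1,1,30.00
0.5,0,1.5,1.20
1.5,0.2,1.5,42.30
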