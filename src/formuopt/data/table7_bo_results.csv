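code,X1,X2,X3,Y2
BO01,1.23,0.14,0.79,45.0
BO02,1.92,0.02,0.64,1.7
BO03,0.81,0.19,1.13,16.4
BO04,1.63,0.15,1.04,49.1
BO05,1.44,0.16,0.9,47.8
BO06,1.55,0.05,1.28,9.6
BO07,1.99,0.175,0.81,46.2
BO08,1.56,0.156,0.85,46.1
BO09,1.85,0.16,1.95,36
BO10,1.7,0.16,0.9,48.5
BO11,1.9,0.16,1.2,48
BO12,2.0,0.14,0.5,48.4
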