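run_order,code,X1,X2,X3
1,BO01,1.23,0.14,0.79
2,BO02,1.92,0.02,0.64
3,BO03,0.81,0.19,1.13
4,BO04,1.63,0.15,1.04
5,BO05,1.44,0.16,0.9
6,BO06,1.55,0.05,1.28
7,BO07,1.99,0.175,0.81
8,BO08,1.56,0.156,0.85
9,BO09,1.85,0.16,1.95
10,BO10,1.7,0.16,0.9
11,BO11,1.9,0.16,1.2
12,BO12,2.0,0.14,0.5
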