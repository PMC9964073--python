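run_order,code,X1,X2,X3,Y1,Y2
1,CC01,1,0.1,1,90,42.7
2,CC02,1,-0.0633,1,56.8,1.5
3,CC03,1,0.1,0.1835,13.9,3.7
4,CC04,1,0.1,1,26,20
5,CC05,0.1835,0.1,1,8.7,1
6,CC06,1,0.1,1.8165,29,1.7
7,CC07,1,0.2633,1,24,1.2
8,CC08,1.8165,0.1,1,28,27.5
9,CC09,1,0.1,1,30,30
10,CC10,1,0.1,1,37.8,32.8
11,CC11,1.5,0.2,0.5,87,42.3
12,CC12,0.5,0.2,0.5,9.8,5
13,CC13,1.5,0,0.5,65.4,46
14,CC14,1,0.1,1,26.3,1.8
15,CC15,0.5,0,1.5,45.1,16.7
16,CC16,1.5,0.2,1.5,31.6,23.1
17,CC17,1.5,0,1.5,6.8,10.6
18,CC18,0.5,0,0.5,11.8,22
19,CC19,1,0.1,1,30,19.8
20,CC20,0.5,0.2,1.5,69.5,43.3
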