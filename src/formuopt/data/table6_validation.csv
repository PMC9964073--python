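trial,X1,X2,X3,predicted_Y1,predicted_Y2,experimental_Y1,experimental_Y2,error_Y1,error_Y2,desirability
1,1.6,0.15,1.0,77.3,46.6,83.2,49.1,7.63,5.3,0.92
2,1.5,0.2,1.5,88.6,47.2,87.0,42.3,1.8,10.3,0.99
3,1.5,0.2,0.5,83.1,49.1,90.0,47.2,8.3,3.8,0.90
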