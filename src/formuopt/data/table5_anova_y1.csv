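term,sum_sq,df,f_value,p_value
Model,11565.2,9,32.96,<0.0001
X1,7151.9,1,183.42,<0.0001
X2,1599.8,1,41.03,0.0001
X3,728.8,1,18.69,0.0019
X1X2,1255.0,1,32.19,0.0003
X1X3,3.6,1,0.09,0.7667
X2X3,220.5,1,5.66,0.0414
X1^2,135.4,1,3.47,0.0953
X2^2,489.7,1,12.56,0.0063
X3^2,2.5,1,0.06,0.8056
Residual,350.9,9,,
Lack of Fit,269.6,5,2.65,0.1829
Pure Error,81.3,4,,
Cor Total,11920.4,19,,
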