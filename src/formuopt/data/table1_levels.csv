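factor,factor_label,coded,actual
X1,PVP/CXB weight ratio,-1.633,0.1835
X1,PVP/CXB weight ratio,-1,0.5
X1,PVP/CXB weight ratio,0,1
X1,PVP/CXB weight ratio,1,1.5
X1,PVP/CXB weight ratio,1.633,1.8165
X2,SLS/CXB weight ratio,-1.633,-0.0633
X2,SLS/CXB weight ratio,-1,0
X2,SLS/CXB weight ratio,0,0.1
X2,SLS/CXB weight ratio,1,0.2
X2,SLS/CXB weight ratio,1.633,0.2633
X3,MAN/CXB weight ratio,-1.633,0.1835
X3,MAN/CXB weight ratio,-1,0.5
X3,MAN/CXB weight ratio,0,1
X3,MAN/CXB weight ratio,1,1.5
X3,MAN/CXB weight ratio,1.633,1.8165
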