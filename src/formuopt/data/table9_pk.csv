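parameter,dose_mg_per_kg,product,mean,sd
cmax,10,nanoformulation,5.51,1.06
cmax,10,celebrex,3.42,0.35
cmax,40,nanoformulation,8.23,0.82
cmax,40,celebrex,5.08,0.38
tmax,10,nanoformulation,1.60,0.55
tmax,10,celebrex,2.60,1.34
tmax,40,nanoformulation,3.80,2.28
tmax,40,celebrex,6.00,3.67
auc_0_24,10,nanoformulation,41.75,5.27
auc_0_24,10,celebrex,41.97,4.27
auc_0_24,40,nanoformulation,110.94,25.22
auc_0_24,40,celebrex,76.42,9.14
auc_0_inf,10,nanoformulation,46.81,4.16
auc_0_inf,10,celebrex,45.30,6.82
auc_0_inf,40,nanoformulation,142.45,41.83
auc_0_inf,40,celebrex,99.27,6.04
t_half,10,nanoformulation,7.35,1.45
t_half,10,celebrex,6.45,1.46
t_half,40,nanoformulation,9.91,4.47
t_half,40,celebrex,10.40,
mrt,10,nanoformulation,7.93,0.39
mrt,10,celebrex,9.21,0.98
mrt,40,nanoformulation,9.33,0.89
mrt,40,celebrex,10.44,0.42
ka,10,nanoformulation,2.38,1.28
ka,10,celebrex,1.76,1.52
ka,40,nanoformulation,2.00,1.60
ka,40,celebrex,0.96,
ke,10,nanoformulation,0.10,0.02
ke,10,celebrex,0.11,0.02
ke,40,nanoformulation,0.08,0.03
ke,40,celebrex,0.07,
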