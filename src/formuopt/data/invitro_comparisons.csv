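metric,medium,test_product,ref_product,test_mean,test_sd,ref_mean,ref_sd,reported_fold,decimals
solubility_ug_per_mL,water,co-milled,pure_powder,8.6,1.06,1.8,0.33,4.8,1
idr_mg_min_cm2,pH1.2+0.2%SLS,co-milled,pure_powder,6.13,0.5,0.0296,0.003,203,0
idr_mg_min_cm2,pH4.5+0.2%SLS,co-milled,pure_powder,6.03,0.6,0.0487,0.002,123,0
idr_mg_min_cm2,pH6.8+0.2%SLS,co-milled,pure_powder,6.43,0.4,0.0667,0.002,96,0
idr_mg_min_cm2,pH12,co-milled,capsule,14.45,1.0,5.61,1.0,2.6,1
idr_mg_min_cm2,pH12,co-milled,physical_mixture,14.45,1.0,1.38,0.4,10,0
idr_mg_min_cm2,pH12,co-milled,pure_powder,14.45,1.0,0.20,0.04,71,0
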