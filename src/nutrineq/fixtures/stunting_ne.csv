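name,family,coefficient,mean,ci,contribution,percent,flags
age_6_12,age,-0.789,0.293,-0.045,-0.009,-4.80,
age_12_18,age,-0.318,0.381,0.050,0.005,2.77,
female,gender,-0.197,0.513,-0.018,-0.002,-0.82,
edu_primary,education,-0.540,0.400,0.019,0.004,1.91,
edu_secondary,education,-0.520,0.291,0.240,0.033,16.65,
wealth_poor,wealth,-0.326,0.260,-0.194,-0.015,-7.57,
wealth_middle,wealth,-0.409,0.243,0.310,0.028,14.16,
wealth_rich,wealth,-0.255,0.120,0.673,0.019,9.43,
wealth_richest,wealth,-1.060,0.104,0.897,0.089,45.43,
cfi_medium,cfi,-0.0370,0.501,-0.009,-0.0001,-0.07,
cfi_high,cfi,0.0120,0.122,0.119,-0.0002,-0.08,
birth_certificate,birth_certificate,0.012,0.650,0.082,-0.001,-0.31,
campaign_access,campaign,-0.295,0.730,0.069,0.013,6.86,
sanitation_improved,sanitation,-0.059,0.325,0.307,0.005,2.71,
water_treatment_adequate,water_treatment,0.031,0.677,0.098,-0.002,-0.95,
water_source_improved,water_source,-0.394,0.590,0.139,0.029,14.67,
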