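name,family,coefficient,mean,ci,contribution,percent,flags
age_6_12,age,0.089,0.2933,-0.0452,-0.0009,0.84,contribution
age_12_18,age,0.0805,0.3805,0.0498,0.0007,-1.09,contribution
female,gender,0.2044,0.5125,-0.0177,0.001,1.33,
edu_primary,education,-0.1442,0.4003,0.0193,0.0006,0.8,
edu_secondary,education,-0.2691,0.2911,0.2395,0.0105,13.44,
wealth_poor,wealth,-0.2222,0.2603,-0.1944,-0.0063,-8.06,
wealth_middle,wealth,-0.3586,0.2434,0.3096,0.0152,19.37,
wealth_rich,wealth,-0.15,0.1195,0.6728,0.0068,8.64,
wealth_richest,wealth,-0.4665,0.1041,0.8966,0.0244,31.21,
cfi_medium,cfi,-0.1935,0.5007,-0.0086,-0.0005,-0.6,
cfi_high,cfi,0.2613,0.1217,0.1192,-0.0021,-2.72,
birth_certificate,birth_certificate,-0.0305,0.6503,0.0823,0.0009,1.17,
campaign_access,campaign,-0.1986,0.7295,0.0694,0.0056,7.2,
sanitation_improved,sanitation,-0.3632,0.3248,0.307,0.0203,25.96,
water_treatment_adequate,water_treatment,0.3806,0.6774,0.0977,-0.0141,-18.06,
water_source_improved,water_source,-0.3535,0.585,0.1387,0.0161,20.56,
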