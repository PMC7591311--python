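name,family,coefficient,mean,ci,contribution,percent,flags
age_6_12,age,-0.927,0.253,-0.018,-0.002,-0.11,percent
age_12_18,age,-0.554,0.402,-0.001,-0.001,-3.36,contribution;percent
female,gender,-0.485,0.488,0.008,0.003,4.31,contribution;percent
edu_primary,education,0.246,0.355,-0.152,0.007,10.42,
edu_secondary,education,-0.13,0.497,0.1682,0.006,9.05,percent
wealth_poor,wealth,-0.052,0.085,-0.836,-0.002,-2.91,
wealth_middle,wealth,0.060,0.233,-0.517,0.004,5.64,
wealth_rich,wealth,-0.477,0.232,-0.051,-0.003,-4.38,
wealth_richest,wealth,-0.365,0.409,0.592,0.047,69.19,
cfi_medium,cfi,0.166,0.624,0.003,-0.001,-0.22,contribution
cfi_high,cfi,0.658,0.153,0.023,-0.001,-1.78,
birth_certificate,birth_certificate,-0.563,0.819,0.026,0.006,9.37,
campaign_access,campaign,-0.095,0.808,-0.013,-0.001,-0.76,
sanitation_improved,sanitation,-0.061,0.674,0.045,0.001,1.44,
water_treatment_adequate,water_treatment,-0.383,0.908,0.015,0.003,4.10,
water_source_improved,water_source,,,,,,
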