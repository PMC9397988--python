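bmi_class,traction_level,T12-L1,L1-L2,L2-L3,L3-L4,L4-L5,L5-S
normal,5,0.028,0.108,0.138,0.113,0.078,0.035
normal,7,0.140,0.682,1.037,0.780,0.588,0.251
normal,9,0.313,1.092,1.686,1.425,1.190,0.772
overweight,5,0.022,0.060,0.058,0.047,0.036,0.016
overweight,7,0.104,0.407,0.564,0.463,0.360,0.184
overweight,9,0.235,1.015,1.454,1.192,0.975,0.484
moderate_obese,5,0.025,0.039,0.034,0.025,0.022,0.013
moderate_obese,7,0.099,0.300,0.385,0.300,0.253,0.164
moderate_obese,9,0.191,0.616,0.829,0.665,0.579,0.416
extreme_obese,5,0.031E-03,0.058E-03,0.058E-03,0.027E-03,0.009E-03,0.003E-03
extreme_obese,7,0.048,0.135,0.114,0.086,0.082,0.075
extreme_obese,9,0.080,0.251,0.343,0.276,0.250,0.193
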