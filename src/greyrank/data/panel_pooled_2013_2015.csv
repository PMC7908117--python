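region,satisfaction,health_exp_pct_gdp,gov_pct_health_exp,oop_pct,beds_per_1000,workforce_per_1000
East China (without Shanghai),68.32,4.24,25.83,31.89,5.96,2.97
Central China,70.53,5.45,32.84,36.87,5.82,2.36
West China (without Chongqing),70.49,6.57,36.54,32.13,5.87,2.38
Northeast China,63.88,5.53,24.51,40.41,6.44,2.67
Beijing,66.10,7.21,25.43,20.45,7.48,5.60
Shanghai,64.33,5.59,20.79,20.22,6.89,4.27
Tianjin,68.84,3.97,25.86,34.20,5.36,3.15
Chongqing,73.94,5.64,31.23,32.22,4.26,1.58
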