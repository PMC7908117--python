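region,satisfaction,health_exp_pct_gdp,gov_pct_health_exp,oop_pct,beds_per_1000,workforce_per_1000
East China (without Shanghai),68.91,4.41,25.48,31.04,6.38,3.16
Central China,72.35,5.54,32.89,35.78,5.75,2.33
West China (without Chongqing),72.29,6.64,36.22,31.28,5.72,2.29
Northeast China,64.46,5.69,24.52,39,6.88,2.78
Beijing,67.22,7.48,24.73,19.42,8.24,5.99
Shanghai,65.45,5.71,20.46,20.69,8.34,4.25
Tianjin,67.66,4.14,26.3,32.73,6.42,3.39
Chongqing,75.45,5.76,31.05,29.97,4.39,1.55
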