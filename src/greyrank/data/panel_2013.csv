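region,satisfaction,health_exp_pct_gdp,gov_pct_health_exp,oop_pct,beds_per_1000,workforce_per_1000
East China (without Shanghai),67.26,3.94,26.46,33.45,5.2,2.62
Central China,66.73,5.26,32.74,39.14,5.97,2.44
West China (without Chongqing),67.01,6.43,37.17,33.77,6.16,2.55
Northeast China,62.88,5.25,24.5,42.84,5.68,2.46
Beijing,63.75,6.66,26.9,22.6,5.89,4.77
Shanghai,62.61,5.41,21.3,19.5,4.68,4.29
Tianjin,70.60,3.72,25.2,36.4,3.77,2.79
Chongqing,71.67,5.45,31.5,35.6,4.06,1.62
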