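country,group_id,tax_type,specific_pct,advalorem_pct,consumption_2006,consumption_2015,price_2006,price_2015,prevalence_pct
Cambodia,1,ad valorem,0,13.15,18.53,22.47,1.34,1.34,18
Nepal,1,specific,16.29,0,3.02,2.7,0.8,1.09,27.1
Bangladesh,1,ad valorem,0,61,19.46,23.02,0.46,0.5,22.3
Myanmar,1,ad valorem,0,50,8.35,7.86,0.24,0.12,23.8
India,2,mixed,42.25,1.27,4.52,3.9,1.28,1.62,13.4
Laos,2,mixed,6.25,1.4,23.67,27.38,0.66,0.68,35.3
Vietnam,2,ad valorem,0,32.5,44.54,47.97,0.82,0.58,18.6
Bhutan,2,none,,,6.55,5.52,0.73,1.18,28.8
Papua New Guinea,2,specific,26.42,0,37.72,25.37,0.93,0.99,26.7
Solomon Islands,2,specific,19.15,0,1.09,0.64,2.89,3.67,19.28
Indonesia,3,mixed,40.91,4.09,33.32,50.52,1.17,1.34,31
Mongolia,3,specific,33.26,0,24.43,36.65,0.83,0.78,24.3
Sri Lanka,3,mixed,59.15,3.91,13.83,11.84,1.49,2.07,12.8
Vanuatu,3,specific,44.44,0,2.32,1.71,3.5,3.53,26
Philippines,4,specific,63.55,0,48.62,42.12,0.79,1.18,20.1
Samoa,4,specific,42.32,0,1.67,1.21,3.79,3.53,37.3
Tonga,4,specific,58.82,0,2.5,1.83,2.89,3.27,35.9
Fiji,5,specific,31.05,0,27.34,19.8,2.16,2.61,10.9
Maldives,5,none,0,0,8.89,7.57,0.78,1.16,24
Thailand,5,mixed,2.86,63.72,30.78,35.92,1.34,1.83,16.1
China,6,mixed,0.6,29.3,74.52,95.94,1.04,2.59,30.5
Malaysia,6,mixed,41.67,8.93,32.51,21.14,2.33,2.97,23
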