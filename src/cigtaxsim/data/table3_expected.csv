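country,dp_max_pct,dp_mean_pct,dc_max_pct,dc_mean_pct,drev_max_pct,drev_mean_pct,smokers_reduced_max,smokers_reduced_mean,sads_averted_max,sads_averted_mean
Cambodia,26.52,6.46,-0.98,-0.24,198.71,48.77,19105,4654,4983,1214
Nepal,25.86,10.71,-0.96,-0.4,156.27,65.09,47965,19865,12974,5373
Bangladesh,17.11,8.72,-0.63,-0.32,27.24,13.93,160793,81947,46839,23871
Myanmar,88.48,20.05,-3.27,-0.74,167.89,39.06,316592,71741,93553,21200
India,23.28,11.74,-3.4,-1.71,48.03,24.67,4028113,2031359,1213670,612049
Laos,21.01,8.85,-3.07,-1.29,262.11,112.45,49408,20812,12382,5216
Vietnam,28.55,6.34,-4.17,-0.93,80.02,18.4,544700,120960,166079,36881
Bhutan,27.15,10.17,-3.96,-1.48,,,6202,2323,1738,651
Papua New Guinea,34.56,12.73,-5.05,-1.86,119.16,45.43,62714,23100,16569,6103
Solomon Islands,39.13,14.46,-5.71,-2.11,186.95,71.8,3915,1447,1001,370
Indonesia,26.77,9.68,-13.06,-4.72,38.65,15.77,7242053,2618718,2303697,833014
Mongolia,31.28,8.65,-15.26,-4.22,66.9,21.46,78062,21587,21569,5964
Sri Lanka,19.99,10.14,-9.76,-4.95,18.85,10.33,199680,101288,71206,36119
Vanuatu,15.38,7.02,-7.51,-3.43,24.51,11.83,1921,877,500,228
Philippines,30.18,7.22,-8.06,-1.93,35.61,9.21,1088283,260351,294598,70477
Samoa,17.29,8.2,-4.62,-2.19,34.35,16.76,2048,972,584,277
Tonga,39.64,10.13,-10.58,-2.7,49.68,14.05,2558,654,747,191
Fiji,24.99,6.58,-15.34,-4.04,52.79,16.3,10603,2792,3342,880
Maldives,34.69,9.01,-21.3,-5.53,,,13551,3520,3366,874
Thailand,12.44,5.18,-7.64,-3.18,9.62,4.35,693909,288943,256608,106851
China,50.96,9.45,-66.45,-12.32,-9.27,15.39,232702235,43152200,86472151,16035358
Malaysia,17.04,7.68,-22.22,-10.01,3.97,3.64,1152312,519352,357217,160999
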