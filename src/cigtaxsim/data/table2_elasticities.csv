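group_id,gni_range,constant,se_constant,beta_price,se_price,beta_gni,se_gni,beta_fctc,se_fctc,n_obs,n_countries,hausman_stat,r_squared,wald_f,members
1,GNI <= US$999,1.435,0.203,-0.037,0.068,-0.161,0.076,0.02,0.012,68,4,60.07,0.256,91.131,Cambodia;Nepal;Bangladesh;Myanmar
2,US$1000-1999,0.919,0.182,-0.146,0.089,0.046,0.061,-0.048,0.005,102,6,7.41,0.533,146.45,India;Laos;Vietnam;Bhutan;Papua New Guinea;Solomon Islands
3,US$2000-2999,-0.072,0.256,-0.488,0.289,0.408,0.078,-0.154,0.027,68,4,34.56,0.919,23.555,Indonesia;Mongolia;Sri Lanka;Vanuatu
4,US$3000-3999,0.831,0.564,-0.267,0.238,0.017,0.165,-0.072,0.023,51,3,34.65,0.849,23.663,Philippines;Samoa;Tonga
5,US$4000-5999,0.269,0.341,-0.614,0.155,0.327,0.098,-0.045,0.023,51,3,39.08,0.657,79.333,Fiji;Maldives;Thailand
6,GNI > US$6000,-0.757,0.552,-1.304,0.306,0.769,0.161,-0.103,0.046,34,2,20.81,0.387,21.077,China;Malaysia
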