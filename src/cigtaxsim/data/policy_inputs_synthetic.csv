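country,specific_share,advalorem_share,prevalence,pop15plus,share_15_29,share_30_39,share_40_49,share_50_59,share_60plus
Cambodia,0,0.1315,0.18,10817319,0.16868070477,0.16868070477,0.16868070477,0.16868070477,0.32527718092
Nepal,0.1629,0,0.271,18498141,0.17638056884,0.17638056884,0.17638056884,0.17638056884,0.294477724641
Bangladesh,0,0.61,0.223,113896397,0.193038427276,0.193038427276,0.193038427276,0.193038427276,0.227846290895
Myanmar,0,0.5,0.238,40632577,0.19640596033,0.19640596033,0.19640596033,0.19640596033,0.214376158682
India,0.4225,0.0127,0.134,884424840,0.205944057296,0.198513985676,0.198513985676,0.198513985676,0.198513985676
Laos,0.0625,0.014,0.353,4562921,0.160499711705,0.160499711705,0.160499711705,0.160499711705,0.358001153181
Vietnam,0,0.325,0.186,70256534,0.222411186697,0.194397203326,0.194397203326,0.194397203326,0.194397203326
Bhutan,,,0.288,543229,0.184192854068,0.184192854068,0.184192854068,0.184192854068,0.263228583728
Papua New Guinea,0.2642,0,0.267,4654998,0.171359307359,0.171359307359,0.171359307359,0.171359307359,0.314562770563
Solomon Islands,0.1915,0,0.1928,355501,0.164561161023,0.164561161023,0.164561161023,0.164561161023,0.341755355909
Indonesia,0.4091,0.0409,0.31,178826493,0.28274251534,0.179314371165,0.179314371165,0.179314371165,0.179314371165
Mongolia,0.3326,0,0.243,2104506,0.181021911336,0.181021911336,0.181021911336,0.181021911336,0.275912354658
Sri Lanka,0.5915,0.0391,0.128,15991539,0.458729281145,0.135317679714,0.135317679714,0.135317679714,0.135317679714
Vanuatu,0.4444,0,0.26,98462,0.167981755986,0.167981755986,0.167981755986,0.167981755986,0.328072976055
Philippines,0.6355,0,0.201,67191561,0.176559951757,0.176559951757,0.176559951757,0.176559951757,0.29376019297
Samoa,0.4232,0,0.373,119023,0.187983539095,0.187983539095,0.187983539095,0.187983539095,0.248065843621
Tonga,0.5882,0,0.359,67354,0.193639143731,0.193639143731,0.193639143731,0.193639143731,0.225443425076
Fiji,0.3105,0,0.109,634008,0.26942284077,0.182644289808,0.182644289808,0.182644289808,0.182644289808
Maldives,0,0,0.24,265117,0.158636363636,0.158636363636,0.158636363636,0.158636363636,0.365454545455
Thailand,0.0286,0.6372,0.161,56427157,0.519083793591,0.120229051602,0.120229051602,0.120229051602,0.120229051602
China,0.006,0.293,0.305,1148136973,0.527314336564,0.118171415859,0.118171415859,0.118171415859,0.118171415859
Malaysia,0.4167,0.0893,0.23,22547332,0.245713229453,0.188571692637,0.188571692637,0.188571692637,0.188571692637
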