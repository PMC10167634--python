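weight_low,weight_high,stratum,RH_150_75,Z_400,Eto_250,burden,auc_rifampicin,auc_isoniazid,auc_pyrazinamide,auc_ethionamide,dev_rifampicin,dev_isoniazid,dev_pyrazinamide,dev_ethionamide
25,26,over_3_months,4,2,2,8,67.3,41.1,421,29.3,0.0,-13.7,0.0,0.0
26,27,over_3_months,4,2,2,8,63.4,40.2,413,28.6,0.0,-15.5,0.0,0.0
27,28,over_3_months,4,2,2,8,61.0,39.2,403,27.7,0.0,-17.6,0.0,0.0
28,29,over_3_months,4,2,2,8,58.2,38.1,393,27.0,0.0,-20.0,0.0,0.0
29,30,over_3_months,4,2,2,8,55.7,37.3,379,26.2,0.0,-21.6,-2.5,0.0
30,31,over_3_months,5,2,2,9,75.8,45.2,372,25.5,0.0,-5.0,-4.3,0.0
31,32,over_3_months,5,2,2,9,71.5,44.0,361,25.2,0.0,-7.6,-7.2,0.0
32,33,over_3_months,5,3,2,10,69.3,43.7,533,24.4,0.0,-8.2,0.0,0.0
33,34,over_3_months,5,3,2,10,68.0,42.5,521,23.9,0.0,-10.7,0.0,0.0
34,35,over_3_months,5,3,2,10,64.3,41.2,510,23.3,0.0,-13.4,0.0,0.0
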