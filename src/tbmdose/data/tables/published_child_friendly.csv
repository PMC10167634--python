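weight_low,weight_high,stratum,RH_75_50,Z_150,Eto_125,burden,auc_rifampicin,auc_isoniazid,auc_pyrazinamide,auc_ethionamide,dev_rifampicin,dev_isoniazid,dev_pyrazinamide,dev_ethionamide
3,4,under_3_months,1.5,0.5,0.5,4,89.6,59.9,371,33.1,14.6,0.8,-4.6,9.8
4,5,under_3_months,1.5,0.5,0.5,4,63.6,50.2,292,26.3,0.0,0.0,-24.9,0.0
3,4,over_3_months,1.5,1,0.5,4,59.3,47.9,521,25.7,0.0,0.0,0.0,0.0
4,5,over_3_months,2,1,0.5,4,68.4,52.8,427,20.8,0.0,0.0,0.0,-5.1
5,6,over_3_months,2.5,1.5,1,6,69.5,54.6,491,32.2,0.0,0.0,0.0,6.8
6,7,over_3_months,3,2,1,6,68.7,56.1,506,25.3,0.0,0.0,0.0,0.0
7,8,over_3_months,3,2,1,6,56.0,50.4,434,21.1,0.0,0.0,0.0,-3.7
8,9,over_3_months,3.5,2.5,1.5,9,62.7,54.3,475,27.5,0.0,0.0,0.0,0.0
9,10,over_3_months,3.5,2.5,1.5,9,58.1,51.6,432,24.7,0.0,0.0,0.0,0.0
10,11,over_3_months,4,3,2,9,65.9,53.5,473,29.8,0.0,0.0,0.0,0.0
11,12,over_3_months,4,3,2,9,61.8,51.0,442,27.4,0.0,0.0,0.0,0.0
12,13,over_3_months,4,3,2,9,56.1,47.3,406,25.6,0.0,-0.6,0.0,0.0
13,14,over_3_months,5,3.5,2,11,73.2,55.3,450,24.1,0.0,0.0,0.0,0.0
14,15,over_3_months,5,3.5,2,11,66.7,53.0,427,22.6,0.0,0.0,0.0,0.0
15,16,over_3_months,5,3.5,2,11,60.2,50.1,403,21.4,0.0,0.0,0.0,-2.4
16,17,over_3_months,6,4,2.5,13,73.4,57.1,438,25.6,0.0,0.0,0.0,0.0
17,18,over_3_months,6,4,2.5,13,68.9,54.6,419,24.5,0.0,0.0,0.0,0.0
18,19,over_3_months,6,4,2.5,13,64.2,52.5,401,23.3,0.0,0.0,0.0,0.0
19,20,over_3_months,6,4,2.5,13,59.2,50.1,386,22.5,0.0,0.0,-0.7,0.0
20,21,over_3_months,7,5,3,15,70.6,56.3,468,26.0,0.0,0.0,0.0,0.0
21,22,over_3_months,7,5,3,15,67.5,54.7,448,25.1,0.0,0.0,0.0,0.0
22,23,over_3_months,7,5,3,15,64.4,52.5,432,24.3,0.0,0.0,0.0,0.0
23,24,over_3_months,7,5,3,15,60.8,51.6,422,23.4,0.0,0.0,0.0,0.0
24,25,over_3_months,7,5,3,15,56.6,49.7,409,22.6,0.0,0.0,0.0,0.0
25,26,over_3_months,9,6,4,19,81.1,61.7,473,29.3,3.7,3.9,0.0,0.0
26,27,over_3_months,9,6,4,19,76.3,60.3,465,28.6,0.0,1.5,0.0,0.0
27,28,over_3_months,9,6,4,19,73.3,58.8,453,27.7,0.0,0.0,0.0,0.0
28,29,over_3_months,9,6,4,19,69.9,57.2,442,27.0,0.0,0.0,0.0,0.0
29,30,over_3_months,9,6,4,19,66.8,56.0,426,26.2,0.0,0.0,0.0,0.0
30,31,over_3_months,10,6,4,20,75.8,60.2,419,25.5,0.0,1.3,0.0,0.0
31,32,over_3_months,10,6,4,20,71.5,58.7,406,25.2,0.0,0.0,0.0,0.0
32,33,over_3_months,10,6,4,20,69.3,58.2,400,24.4,0.0,0.0,0.0,0.0
33,34,over_3_months,10,6,4,20,68.0,56.7,390,23.9,0.0,0.0,0.0,0.0
34,35,over_3_months,10,6,4,20,64.3,55.0,383,23.3,0.0,0.0,-1.5,0.0
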