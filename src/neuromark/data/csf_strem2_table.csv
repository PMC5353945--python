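subject_id,group,sex,onset_age_years,duration_years,sampling_age_printed,percent_course,strem2_ng_ml
ALS01,ALS,M,35.8,4.8,36.9,22.8,309.6
ALS02,ALS,M,50.7,17.0,53.4,16.2,2.6
ALS03,ALS,M,79.7,1.3,79.8,6.3,10.3
ALS04,ALS,M,67.4,11.9,72.1,39.2,10.8
ALS05,ALS,M,71.5,0.8,72.3,90.0,5.7
ALS06,ALS,F,47.8,14.5,49.3,10.9,3.6
ALS07,ALS,F,65.3,1.2,66.3,85.7,7.9
ALS08,ALS,M,64.4,1.0,65.3,100.0,6.9
ALS09,ALS,M,64.3,0.8,64.8,66.7,2.3
ALS10,ALS,F,34.4,0.6,34.7,42.9,4.7
ALS11,ALS,M,54.4,6.9,56.1,24.1,9.0
ALS12,ALS,M,52.6,5.4,54.0,26.2,27.4
ALS13,ALS,M,56.4,12.0,57.8,11.8,4.2
ALS14,ALS,F,76.2,1.0,76.9,75.0,4.9
ALS15,ALS,F,64.3,0.4,64.5,60.0,8.1
ALS16,ALS,M,69.4,0.7,69.7,37.5,37.7
ALS17,ALS,M,42.9,10.5,43.9,9.5,5.3
ALS18,ALS,M,47.1,1.3,47.7,43.8,18.4
ALS19,ALS,F,54.2,5.8,54.7,8.7,14.5
ALS20,ALS,M,57.7,1.1,58.0,30.8,14.8
ALS21,ALS,F,51.2,5.6,52.3,19.4,22.8
ALS22,ALS,F,45.2,8.6,46.0,9.7,8.6
ALS23,ALS,F,59.5,1.4,59.8,17.6,9.9
ALS24,ALS,M,36.8,4.4,38.7,43.4,8.5
ALS25,ALS,M,32.0,8.8,37.9,67.0,18.2
ALS26,ALS,F,50.7,3.8,51.7,26.7,2.9
ALS27,ALS,M,29.8,4.5,31.5,38.9,2.8
ALS28,ALS,F,68.5,2.5,69.9,56.7,4.0
ALS29,ALS,M,81.0,1.6,82.5,94.7,4.3
ALS30,ALS,M,64.3,4.5,67.6,72.2,25.1
ALS31,ALS,M,50.6,2.2,51.4,38.5,16.5
ALS32,ALS,M,65.1,3.6,67.7,72.1,9.7
ALS33,ALS,F,58.7,1.3,59.6,73.3,16.0
ALS34,ALS,M,59.2,5.2,62.1,56.5,9.4
ALS35,ALS,F,60.5,1.7,61.6,65.0,24.8
ALS36,ALS,M,55.7,1.8,56.9,71.4,16.2
ALS37,ALS,M,60.1,4.8,62.8,57.9,9.0
ALS38,ALS,M,65.5,2.4,66.5,41.4,5.1
ALS39,ALS,F,49.9,3.8,52.5,67.4,17.1
ALS40,ALS,F,,,63.8,,8.3
ALS41,ALS,F,52.9,3.4,54.3,41.5,5.1
ALS42,ALS,M,50.8,2.6,51.4,25.8,7.3
ALS43,ALS,F,62.1,7.7,68.3,80.4,34.9
ALS44,ALS,M,32.9,2.6,33.9,38.7,4.7
ALS45,ALS,F,47.3,1.7,47.8,30.0,4.4
ALS46,ALS,M,66.6,3.9,69.6,76.6,7.9
CTL01,Control,M,,,828,,4.0
CTL02,Control,M,,,407,,6.5
CTL03,Control,F,,,717,,10.6
CTL04,Control,F,,,671,,7.0
CTL05,Control,F,,,628,,2.9
CTL06,Control,M,,,573,,3.4
CTL07,Control,F,,,542,,2.6
CTL08,Control,F,,,563,,4.8
CTL09,Control,M,,,455,,5.9
CTL10,Control,M,,,586,,4.8
CTL11,Control,M,,,473,,14.2
CTL12,Control,F,,,587,,3.1
CTL13,Control,F,,,594,,12.9
CTL14,Control,M,,,886,,9.4
CTL15,Control,M,,,782,,14.7
CTL16,Control,M,,,553,,12.3
CTL17,Control,M,,,502,,5.1
CTL18,Control,F,,,701,,8.9
CTL19,Control,M,,,673,,6.7
CTL20,Control,F,,,475,,3.4
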