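focus,partner,n_times,years,total,percent
ER,n-TNM,2,"5, 10",6,33.33
ER,HER2,2,"5, 15",6,33.33
ER,LN positive,2,"15, 15",6,33.33
TNEG,HER2,1,"5",7,14.29
TNEG,Age at DG,1,"15",7,14.29
TNEG,LN positive/status,2,"15",7,28.57
TNEG,Ethnicity,1,"15",7,14.29
TNEG,Stage,1,"15",7,14.29
TNEG,Re_excision,1,"15",7,14.29
HER2,Stage,6,"5, 5, 10, 10, 10, 15",23,26.09
HER2,MRIs_60_surgery,1,"5",23,4.35
HER2,ER_percent,1,"5",23,4.35
HER2,TNEG,1,"5",23,4.35
HER2,Histology,3,"5, 10, 10",23,13.04
HER2,Grade,2,"5, 5",23,8.70
HER2,Invasive tumor location,2,"5, 10",23,8.70
HER2,ER,1,"5, 15",23,4.35
HER2,PR,2,"5, 10",23,8.70
HER2,LN positive/status,3,"10, 10, 15",23,13.04
HER2,Surgical margins,1,"10",23,4.35
Race/ethnicity,Histology,1,"5",8,12.50
Race/ethnicity,Grade,1,"5",8,12.50
Race/ethnicity,ER_percent,1,"10",8,12.50
Race/ethnicity,n-TNM,1,"10",8,12.50
Race/ethnicity,Side,1,"10",8,12.50
Race/ethnicity,LN positive/status,1,"10",8,12.50
Race/ethnicity,TNEG,1,"15",8,12.50
Race/ethnicity,Stage,1,"15",8,12.50
Alcohol/smoking,LN positive/status,1,"15",1,100.00
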