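focus,partner,n_times,years,total,percent
ER,n-TNM,9,"5, 5, 5, 5, 5, 5, 5, 10, 15",30,30.00
ER,Surgical margins,4,"5, 5, 10, 15",30,13.33
ER,Family history,2,"5, 10",30,6.67
ER,LN positive/status,4,"5, 10, 15, 15",30,13.33
ER,HER2,1,"5",30,3.33
ER,MRIs_60_surgery,1,"5",30,3.33
ER,Race/ethnicity,3,"5, 15, 15",30,10.00
ER,Histology,1,"5",30,3.33
ER,Invasive tumor location,1,"5",30,3.33
ER,Size,1,"5",30,3.33
ER,Side,1,"5",30,3.33
ER,DCIS_level,2,"5, 10",30,6.67
TNEG,n-TNM,4,"5, 5, 10, 15",8,50.00
TNEG,Surgical margins,2,"10, 15",8,25.00
TNEG,Smoking,1,"5",8,12.50
TNEG,Invasive tumor location,1,"5",8,12.50
HER2,ER,1,"5",12,8.33
HER2,n-TNM,1,"5",12,8.33
HER2,Stage,5,"5, 10, 10, 10, 15",12,41.67
HER2,Surgical margins,2,"5, 10",12,16.67
HER2,Histology,1,"10",12,8.33
HER2,Grade,1,"15",12,8.33
HER2,PR,1,"10",12,8.33
Race/ethnicity,ER,3,"5, 15, 15",17,17.65
Race/ethnicity,n-TNM,3,"5, 10, 15",17,17.65
Race/ethnicity,Stage,3,"5, 15, 15",17,17.65
Race/ethnicity,Surgical margins,1,"5",17,5.88
Race/ethnicity,ER_percent,1,"10",17,5.88
Race/ethnicity,Grade,1,"15",17,5.88
Race/ethnicity,LN positive/status,3,"15",17,17.65
Race/ethnicity,Re_excision,1,"15",17,5.88
Race/ethnicity,PR_percent,1,"15",17,5.88
Smoking/alcohol,TNEG,1,"5",4,25.00
Smoking/alcohol,n-TNM,1,"5",4,25.00
Smoking/alcohol,Stage,1,"10",4,25.00
Smoking/alcohol,Histology,1,"10",4,25.00
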