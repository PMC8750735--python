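focus,partner,n_times,years,total,percent
ER,n-TNM,6,"5, 5, 5, 10, 10, 10",19,31.58
ER,Surgical margins,3,"5, 5, 10",19,15.79
ER,Race,3,"5, 10, 15",19,15.79
ER,Size,1,"5",19,5.26
ER,Smoking,1,"5",19,5.26
ER,Family history,1,"10",19,5.26
ER,LN positive/status,1,"10",19,5.26
ER,Stage,1,"10",19,5.26
ER,DCIS_level,1,"10",19,5.26
ER,Age at DG,1,"10",19,5.26
TNEG,n-TNM,1,"10",2,50.00
TNEG,Surgical margins,1,"10",2,50.00
HER2,Stage,2,"5, 10",7,28.57
HER2,Surgical margins,4,"5, 5, 10",7,57.14
HER2,t-TNM,1,"5",7,14.29
Race/ethnicity,Stage,6,"5, 15, 15, 15, 15, 15",22,27.27
Race/ethnicity,Surgical margins,2,"5, 5",22,9.09
Race/ethnicity,ER,3,"5, 10, 15",22,13.64
Race/ethnicity,n-TNM,3,"5, 10, 10",22,13.64
Race/ethnicity,Family history,1,"10",22,4.55
Race/ethnicity,LN positive/status,1,"10",22,4.55
Race/ethnicity,ER_percent,1,"10",22,4.55
Race/ethnicity,Grade,1,"15",22,4.55
Race/ethnicity,Invasive tumor location,1,"15",22,4.55
Race/ethnicity,Re-excision,1,"15",22,4.55
Race/ethnicity,Alcohol,1,"15",22,4.55
Race/ethnicity,Histology2,1,"15",22,4.55
Smoking/alcohol,t-TNM,2,"5, 5",12,16.67
Smoking/alcohol,n-TNM,3,"5, 5, 5",12,25.00
Smoking/alcohol,Stage,3,"5, 10, 15",12,25.00
Smoking/alcohol,Surgical margins,2,"5, 10",12,16.67
Smoking/alcohol,ER,1,"5",12,8.33
Smoking/alcohol,race,1,"15",12,8.33
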