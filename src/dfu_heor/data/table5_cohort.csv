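study_id,gender,age,ethnicity,bmi,employment,smoking,diabetes_type,year_diagnosis,monofilament_loss,sinbad_score,dfu_study_visits,reason_incomplete,gp_visits,outpatient_visits,hospital_bed_days
001,M,75,English,37.6,Retired,Previous,2,1992,Both,2,2,Reulceration,0,0,0
002,M,72,English,29.1,Retired,Previous,1,1996,Both,2,7,,4,3,3
004,M,68,English,37.2,Retired,Never,2,2006,Both,4,3,Reulceration,1,0,0
005,M,62,English,35.6,Full time,Previous,2,1997,Both,2,5,Lost to FU,4,0,0
009,F,49,English,31,Full time,Never,2,2008,None,2,7,,1,8,0
010,F,53,English,31,Full time,Previous,1,1985,None,2,6,Lost to FU,1,4,0
011,M,70,English,34.2,Retired,Current,2,2017,Right,1,3,Withdrew,1,0,0
012,M,73,English,24.1,Retired,Never,2,2016,Both,2,5,Reulceration,1,1,0
013,M,61,English,45.6,Benefits,Previous,2,2007,Both,1,3,Reulceration,0,0,0
014,M,51,English,44.3,Full time,Never,2,2007,Both,1,3,Reulceration,1,0,0
015,M,66,English,29.1,Retired,Previous,2,1980,Both,1,1,Withdrew,0,0,0
016,M,51,English,27.7,Full time,Never,2,2004,None,3,3,Withdrew,0,0,0
017,M,56,English,27.6,Full time,Previous,2,2007,Both,1,4,Lost to FU,1,0,0
018,M,51,English,29.7,Benefits,Previous,1,2000,Both,4,3,Withdrew,0,0,0
019,F,54,English,30.3,Full time,Previous,2,2004,Both,3,3,Reulceration,0,0,0
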