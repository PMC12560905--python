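ear_tag,test_date,parity,season,dim,dmy_kg,my_morn_kg,my_noon_kg,my_night_kg,fat_pct,protein_pct,bw_kg
C01,2023-03-10,2,spring,40,27.5,9.1,9.3,9.1,3.90,3.30,575
C01,2023-04-12,2,spring,73,28.2,9.4,9.5,9.3,3.95,3.35,575
C02,2023-03-11,2,spring,45,29.0,9.6,9.8,9.6,3.88,3.28,590
C02,2023-04-14,2,spring,79,30.1,10.0,10.1,10.0,3.92,3.31,590
C03,2023-03-12,2,spring,50,26.4,8.7,8.9,8.8,4.00,3.40,560
C03,2023-04-15,2,spring,84,27.0,9.0,9.0,9.0,3.97,3.37,560
C04,2023-03-13,2,spring,55,31.0,10.3,10.4,10.3,3.85,3.25,610
C04,2023-04-16,2,spring,89,30.5,10.1,10.2,10.2,3.89,3.29,610
C05,2023-03-14,2,spring,60,28.8,9.5,9.7,9.6,3.93,3.33,585
C05,2023-04-17,2,spring,94,29.3,9.7,9.8,9.8,3.91,3.32,585
C06,2023-03-15,2,spring,65,27.9,9.2,9.4,9.3,3.96,3.36,570
C06,2023-04-18,2,spring,99,28.4,9.4,9.5,9.5,3.94,3.34,570
,2023-03-20,2,spring,70,28.0,9.3,9.4,9.3,3.90,3.30,580
C07,not-a-date,2,spring,75,28.0,9.3,9.4,9.3,3.90,3.30,580
C08,2023-03-21,,spring,80,28.0,9.3,9.4,9.3,3.90,3.30,580
C09,2023-03-22,2,spring,85,28.0,,,,3.90,3.30,
C02,2023-03-11,2,spring,45,29.0,9.6,9.8,9.6,,3.28,590
C10,2023-03-23,2,spring,90,1.0,0.3,0.4,0.3,3.90,3.30,580
C11,2023-03-24,2,spring,95,75.0,25.0,25.0,25.0,3.90,3.30,580
C12,2023-03-25,2,spring,350,28.0,9.3,9.4,9.3,3.90,3.30,580
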