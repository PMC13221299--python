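subject_id,wave,date,sedentary_min,light_min,moderate_min,vigorous_min,monitored_min,steps,sleep_min
S1,1,2021-01-04,1020,250,60,30,1360,8000,480
S1,1,2021-01-05,1020,250,60,30,1360,8000,480
S1,1,2021-01-06,1020,250,60,30,1360,8000,480
S1,1,2021-01-07,1020,250,60,30,1360,8000,470
S1,1,2021-01-08,1020,250,60,30,1360,8200,480
S1,1,2021-01-09,1020,250,60,30,1360,7800,490
S1,1,2021-01-10,1020,250,60,30,1360,8100,475
S1,1,2021-01-11,1020,250,60,30,1360,7900,485
S1,1,2021-01-12,1020,250,60,30,1360,8000,480
S1,1,2021-01-13,1020,250,60,30,1360,8000,480
S1,1,2021-01-14,1020,250,60,30,1360,8000,480
S2,1,2021-01-04,1020,250,60,30,1360,8000,480
S2,1,2021-01-05,1020,250,60,30,1360,8000,480
S2,1,2021-01-06,1020,250,60,30,1360,8000,480
S2,1,2021-01-07,800,200,70,30,1100,8000,480
S2,1,2021-01-08,1070,100,20,10,1200,7000,475
S2,1,2021-01-09,1020,250,60,30,1360,8050,480
S2,1,2021-01-10,1020,250,60,30,1360,7950,478
S2,1,2021-01-11,1020,250,60,30,1360,8000,482
S2,1,2021-01-12,1020,250,60,30,1360,8000,480
S2,1,2021-01-13,1020,250,60,30,1360,8000,480
S2,1,2021-01-14,1020,250,60,30,1360,8000,480
S3,1,2021-01-04,1020,250,60,30,1360,8000,480
S3,1,2021-01-05,1020,250,60,30,1360,8000,480
S3,1,2021-01-06,1020,250,60,30,1360,8000,480
S3,1,2021-01-07,1020,250,60,30,1360,8150,460
S3,1,2021-01-08,1020,250,60,30,1360,7850,490
S3,1,2021-01-09,1020,250,60,30,1360,40000,480
S3,1,2021-01-10,1020,250,60,30,1360,8000,900
S3,1,2021-01-11,1020,250,60,30,1360,8000,470
S3,1,2021-01-12,1020,250,60,30,1360,8000,480
S3,1,2021-01-13,1020,250,60,30,1360,8000,480
S3,1,2021-01-14,1020,250,60,30,1360,8000,480
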