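participant_id,night_date,longest_gap_hours,adequate
p00000,2022-02-28,11.0000,True
p00000,2022-03-01,8.0653,True
p00000,2022-03-02,6.5050,True
p00000,2022-03-03,7.7442,True
p00000,2022-03-04,11.0000,True
p00001,2022-02-28,11.0000,True
p00001,2022-03-01,6.1856,True
p00001,2022-03-02,5.9461,False
p00001,2022-03-03,7.2603,True
p00001,2022-03-04,11.0000,True
p00002,2022-02-28,11.0000,True
p00002,2022-03-01,8.1875,True
p00002,2022-03-02,7.1836,True
p00002,2022-03-03,10.3903,True
p00002,2022-03-04,11.0000,True
p00003,2022-02-28,11.0000,True
p00003,2022-03-01,6.8800,True
p00003,2022-03-02,7.0408,True
p00003,2022-03-03,7.4167,True
p00004,2022-02-28,11.0000,True
p00004,2022-03-01,5.5469,False
p00004,2022-03-02,6.2697,True
p00004,2022-03-03,6.3836,True
p00004,2022-03-04,11.0000,True
p00005,2022-02-28,11.0000,True
p00005,2022-03-01,4.9164,False
p00005,2022-03-02,5.7908,False
p00005,2022-03-03,5.4167,False
p00005,2022-03-04,11.0000,True
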