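participant_id,date,total_hours,hours_A,hours_B,hours_C,hours_D,hours_E,hours_unknown,session_count,count_A,count_B,count_C,count_D,count_E,count_unknown
p00000,2022-03-01,1.0950,0.0889,0.1347,0.1514,0.6589,0.0611,0.0000,14,1,3,2,7,1,0
p00000,2022-03-02,0.9983,0.0358,0.0269,0.0508,0.8236,0.0186,0.0425,18,1,1,1,13,1,1
p00000,2022-03-03,1.3475,0.0375,0.2369,0.1042,0.3361,0.4250,0.2078,18,1,4,3,6,2,2
p00000,2022-03-04,0.2156,0.0000,0.2156,0.0000,0.0000,0.0000,0.0000,1,0,1,0,0,0,0
p00001,2022-03-01,0.8161,0.0000,0.3350,0.1167,0.2511,0.1133,0.0000,6,0,2,2,1,1,0
p00001,2022-03-02,0.3239,0.0158,0.1539,0.0167,0.1375,0.0000,0.0000,8,1,2,1,4,0,0
p00001,2022-03-03,0.1217,0.0806,0.0411,0.0000,0.0000,0.0000,0.0000,4,1,3,0,0,0,0
p00001,2022-03-04,0.0133,0.0000,0.0000,0.0133,0.0000,0.0000,0.0000,1,0,0,1,0,0,0
p00002,2022-03-01,2.1506,0.7322,0.6206,0.1394,0.6583,0.0000,0.0000,17,4,3,2,8,0,0
p00002,2022-03-02,0.7433,0.0472,0.0550,0.0528,0.3783,0.1414,0.0686,12,1,1,1,6,1,2
p00002,2022-03-03,0.6067,0.0000,0.0300,0.0000,0.3692,0.0000,0.2075,9,0,1,0,4,0,4
p00002,2022-03-04,0.0411,0.0411,0.0000,0.0000,0.0000,0.0000,0.0000,1,1,0,0,0,0,0
p00003,2022-03-01,1.2944,0.5947,0.2114,0.0669,0.1514,0.2700,0.0000,9,2,1,2,3,1,0
p00003,2022-03-02,0.4053,0.0511,0.1417,0.0172,0.0933,0.0000,0.1019,11,1,2,1,6,0,1
p00003,2022-03-03,0.8736,0.0997,0.3986,0.3056,0.0289,0.0408,0.0000,12,3,3,4,1,1,0
p00004,2022-03-01,1.4592,0.3761,0.0844,0.3022,0.5819,0.0122,0.1022,20,5,1,3,9,1,1
p00004,2022-03-02,1.2053,0.0733,0.4061,0.2103,0.3542,0.0717,0.0897,28,2,7,3,12,2,2
p00004,2022-03-03,1.6197,0.0442,0.0656,0.0331,1.3311,0.1325,0.0133,18,2,2,1,10,2,1
p00004,2022-03-04,0.0522,0.0000,0.0000,0.0000,0.0522,0.0000,0.0000,1,0,0,0,1,0,0
p00005,2022-03-01,1.4769,0.1333,0.1625,0.0000,0.7467,0.4344,0.0000,14,2,3,0,6,3,0
p00005,2022-03-02,1.5528,0.2061,0.2275,0.1917,0.7339,0.0678,0.1258,17,1,3,3,6,2,2
p00005,2022-03-03,2.6517,0.0000,0.9547,0.5339,1.0739,0.0892,0.0000,27,0,6,7,12,2,0
p00005,2022-03-04,0.0750,0.0000,0.0000,0.0583,0.0000,0.0000,0.0167,2,0,0,1,0,0,1
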