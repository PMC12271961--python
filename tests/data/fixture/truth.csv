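participant_id,night_date,onset,wake,onset_h,wake_h,true_sleep_in_window_hours
p00000,2022-03-01,2022-03-01T21:56:05,2022-03-02T05:59:14,457269.934601,457277.987295,8.052694
p00000,2022-03-02,2022-03-02T22:46:15,2022-03-03T06:34:34,457294.770902,457302.575975,7.229098
p00000,2022-03-03,2022-03-03T22:15:21,2022-03-04T06:39:07,457318.255949,457326.651976,7.744051
p00001,2022-03-01,2022-03-01T22:38:26,2022-03-02T04:47:15,457270.640664,457276.787386,6.146723
p00001,2022-03-02,2022-03-02T22:33:32,2022-03-03T06:12:44,457294.558853,457302.212157,7.441147
p00001,2022-03-03,2022-03-03T22:28:45,2022-03-04T05:41:19,457318.479084,457325.688654,7.209570
p00002,2022-03-01,2022-03-01T23:10:44,2022-03-02T06:15:45,457271.179018,457278.262361,6.820982
p00002,2022-03-02,2022-03-02T22:39:06,2022-03-03T05:46:58,457294.651627,457301.782843,7.131216
p00002,2022-03-03,2022-03-03T22:23:47,2022-03-04T06:28:38,457318.396478,457326.477166,7.603522
p00003,2022-03-01,2022-03-01T22:14:10,2022-03-02T05:06:08,457270.236170,457277.102237,6.866067
p00003,2022-03-02,2022-03-02T22:57:33,2022-03-03T06:21:17,457294.959202,457302.354754,7.040798
p00003,2022-03-03,2022-03-03T22:35:00,2022-03-04T04:53:52,457318.583393,457324.897646,6.314252
p00004,2022-03-01,2022-03-02T00:27:11,2022-03-02T06:35:24,457272.453019,457278.589971,5.546981
p00004,2022-03-02,2022-03-02T23:43:49,2022-03-03T06:49:32,457295.730242,457302.825505,6.269758
p00004,2022-03-03,2022-03-03T23:30:50,2022-03-04T06:35:29,457319.513882,457326.591497,6.486118
p00005,2022-03-01,2022-03-02T01:05:01,2022-03-02T08:37:25,457273.083584,457280.623692,4.916416
p00005,2022-03-02,2022-03-03T00:12:33,2022-03-03T07:28:51,457296.209053,457303.480935,5.790947
p00005,2022-03-03,2022-03-04T00:35:00,2022-03-04T08:27:13,457320.583358,457328.453722,5.416642
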