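participant_id,n_days,mean_total_hours,median_total_hours,mean_session_count,mean_hours_A,median_hours_A,mean_hours_B,median_hours_B,mean_hours_C,median_hours_C,mean_hours_D,median_hours_D,mean_hours_E,median_hours_E,mean_hours_unknown,median_hours_unknown
p00000,4,0.9141,1.0467,12.7500,0.0406,0.0367,0.1535,0.1751,0.0766,0.0775,0.4547,0.4975,0.1262,0.0399,0.0626,0.0213
p00001,4,0.3187,0.2228,4.7500,0.0241,0.0079,0.1325,0.0975,0.0367,0.0150,0.0972,0.0688,0.0283,0.0000,0.0000,0.0000
p00002,4,0.8854,0.6750,9.7500,0.2051,0.0442,0.1764,0.0425,0.0481,0.0264,0.3515,0.3737,0.0353,0.0000,0.0690,0.0343
p00003,3,0.8578,0.8736,10.6667,0.2485,0.0997,0.2506,0.2114,0.1299,0.0669,0.0912,0.0933,0.1036,0.0408,0.0340,0.0000
p00004,4,1.0841,1.3322,16.7500,0.1234,0.0587,0.1390,0.0750,0.1364,0.1217,0.5799,0.4681,0.0541,0.0419,0.0513,0.0515
p00005,4,1.4391,1.5149,15.0000,0.0849,0.0667,0.3362,0.1950,0.1960,0.1250,0.6386,0.7403,0.1478,0.0785,0.0356,0.0083
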