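participant_id,n_nights,mean_gap_hours,median_gap_adequate_nights,prop_adequate,stratum
p00000,5,8.8629,8.0653,1.0000,group2
p00001,5,8.2784,9.1301,0.8000,group2
p00002,5,9.5523,10.3903,1.0000,group2
p00003,4,8.0844,7.2288,1.0000,group2
p00004,5,8.0401,8.6918,0.8000,group2
p00005,5,7.6248,11.0000,0.4000,group2
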