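grouping,level,n,n_group1,pct_group1,n_group2,g2_median_gap_hours,g2_gap_q1,g2_gap_q3,g2_pct_adequate_nights
all,all,6,0,0.0000,6,8.9110,8.2219,10.0752,90.0000
gender,female,4,0,0.0000,4,9.5410,8.5352,10.5427,90.0000
gender,male,2,0,0.0000,2,8.1794,7.7041,8.6548,90.0000
age_range,18-<35,4,0,0.0000,4,9.7602,9.0206,10.5427,80.0000
age_range,35-<60,2,0,0.0000,2,7.6470,7.4379,7.8561,100.0000
highest_degree,bachelor,2,0,0.0000,2,8.1794,7.7041,8.6548,90.0000
highest_degree,high_school,4,0,0.0000,4,9.5410,8.5352,10.5427,90.0000
employment,in_education,3,0,0.0000,3,9.1301,8.5977,10.0651,80.0000
employment,part_time,1,0,0.0000,1,8.6918,8.6918,8.6918,80.0000
employment,full_time,2,0,0.0000,2,8.8095,8.0191,9.5999,100.0000
use_type,mainly_private,6,0,0.0000,6,8.9110,8.2219,10.0752,90.0000
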