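variable,grouping,group_i,group_j,z,p_raw,p_adjusted
mean_total_hours,gender,female,male,1.8516,0.0641,0.0641
mean_total_hours,age_range,18-<35,35-<60,0.4629,0.6434,0.6434
mean_total_hours,highest_degree,bachelor,high_school,-1.8516,0.0641,0.0641
mean_total_hours,employment,in_education,part_time,-0.6172,0.5371,0.9890
mean_total_hours,employment,in_education,full_time,0.6831,0.4945,0.9890
mean_total_hours,employment,part_time,full_time,1.0911,0.2752,0.8257
mean_hours_A,gender,female,male,0.0000,1.0000,1.0000
mean_hours_A,age_range,18-<35,35-<60,-0.4629,0.6434,0.6434
mean_hours_A,highest_degree,bachelor,high_school,0.0000,1.0000,1.0000
mean_hours_A,employment,in_education,part_time,-0.9258,0.3545,0.7091
mean_hours_A,employment,in_education,full_time,-2.0494,0.0404,0.1213
mean_hours_A,employment,part_time,full_time,-0.6547,0.5127,0.7091
mean_hours_B,gender,female,male,0.4629,0.6434,0.6434
mean_hours_B,age_range,18-<35,35-<60,-0.4629,0.6434,0.6434
mean_hours_B,highest_degree,bachelor,high_school,-0.4629,0.6434,0.6434
mean_hours_B,employment,in_education,part_time,0.6172,0.5371,0.9890
mean_hours_B,employment,in_education,full_time,-0.6831,0.4945,0.9890
mean_hours_B,employment,part_time,full_time,-1.0911,0.2752,0.8257
mean_hours_C,gender,female,male,0.9258,0.3545,0.3545
mean_hours_C,age_range,18-<35,35-<60,0.0000,1.0000,1.0000
mean_hours_C,highest_degree,bachelor,high_school,-0.9258,0.3545,0.3545
mean_hours_C,employment,in_education,part_time,-0.7715,0.4404,1.0000
mean_hours_C,employment,in_education,full_time,0.1952,0.8453,1.0000
mean_hours_C,employment,part_time,full_time,0.8729,0.3827,1.0000
mean_hours_D,gender,female,male,1.8516,0.0641,0.0641
mean_hours_D,age_range,18-<35,35-<60,0.9258,0.3545,0.3545
mean_hours_D,highest_degree,bachelor,high_school,-1.8516,0.0641,0.0641
mean_hours_D,employment,in_education,part_time,-0.4629,0.6434,0.6434
mean_hours_D,employment,in_education,full_time,1.1711,0.2416,0.5713
mean_hours_D,employment,part_time,full_time,1.3093,0.1904,0.5713
mean_hours_E,gender,female,male,0.9258,0.3545,0.3545
mean_hours_E,age_range,18-<35,35-<60,-0.9258,0.3545,0.3545
mean_hours_E,highest_degree,bachelor,high_school,-0.9258,0.3545,0.3545
mean_hours_E,employment,in_education,part_time,0.4629,0.6434,1.0000
mean_hours_E,employment,in_education,full_time,0.5855,0.5582,1.0000
mean_hours_E,employment,part_time,full_time,0.0000,1.0000,1.0000
mean_gap_hours,gender,female,male,0.0000,1.0000,1.0000
mean_gap_hours,age_range,18-<35,35-<60,-0.4629,0.6434,0.6434
mean_gap_hours,highest_degree,bachelor,high_school,0.0000,1.0000,1.0000
mean_gap_hours,employment,in_education,part_time,0.6172,0.5371,0.9890
mean_gap_hours,employment,in_education,full_time,-0.6831,0.4945,0.9890
mean_gap_hours,employment,part_time,full_time,-1.0911,0.2752,0.8257
prop_adequate,gender,female,male,-0.2500,0.8026,0.8026
prop_adequate,age_range,18-<35,35-<60,-1.5000,0.1336,0.1336
prop_adequate,highest_degree,bachelor,high_school,0.2500,0.8026,0.8026
prop_adequate,employment,in_education,part_time,0.1667,0.8676,0.8676
prop_adequate,employment,in_education,full_time,-1.3703,0.1706,0.5118
prop_adequate,employment,part_time,full_time,-1.1785,0.2386,0.5118
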