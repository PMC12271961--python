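grouping,level,n,pct
gender,female,4,66.7000
gender,male,2,33.3000
gender,excluded,0,0.0000
age_range,<18,0,0.0000
age_range,18-<35,4,66.7000
age_range,35-<60,2,33.3000
age_range,>=60,0,0.0000
age_range,excluded,0,0.0000
highest_degree,doctorate,0,0.0000
highest_degree,master,0,0.0000
highest_degree,bachelor,2,33.3000
highest_degree,secondary,0,0.0000
highest_degree,high_school,4,66.7000
highest_degree,none,0,0.0000
highest_degree,excluded,0,0.0000
employment,in_education,3,50.0000
employment,unemployed,0,0.0000
employment,part_time,1,16.7000
employment,full_time,2,33.3000
employment,self_employed,0,0.0000
employment,homemaker,0,0.0000
employment,retired,0,0.0000
employment,excluded,0,0.0000
use_type,both_equally,0,0.0000
use_type,mainly_private,6,100.0000
use_type,mainly_work,0,0.0000
use_type,private_only,0,0.0000
use_type,work_only,0,0.0000
use_type,excluded,0,0.0000
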