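grouping,level,n_group1,n_total,printed_pct
all,all,86,1074,8
gender,male,41,350,12
gender,female,45,724,6
employment,self_employed,7,41,17
employment,in_education,50,535,9
use_type,work_only,2,7,29
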