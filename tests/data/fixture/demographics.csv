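participant_id,gender,age,highest_degree,employment,use_type
p00000,female,42,high_school,in_education,mainly_private
p00001,male,27,bachelor,in_education,mainly_private
p00002,female,21,high_school,full_time,mainly_private
p00003,male,36,bachelor,full_time,mainly_private
p00004,female,24,high_school,part_time,mainly_private
p00005,female,26,high_school,in_education,mainly_private
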