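grouping,subgroup,predictor,n,r,p,slope,intercept,r_squared,p_slope
gender,female,total,4,-0.8858,0.1142,-2.9904,11.7516,0.7847,0.1142
gender,female,A,4,0.5025,0.4975,6.1810,7.8185,0.2525,0.4975
gender,female,B,4,-0.5653,0.4347,-5.3240,9.5916,0.3196,0.4347
gender,female,C,4,-0.9737,0.0263,-12.7256,9.9739,0.9481,0.0263
gender,female,D,4,-0.9999,0.0001,-6.6848,11.9035,0.9999,0.0001
gender,female,E,4,-0.5587,0.4413,-8.7997,9.3196,0.3121,0.4413
age_range,18-<35,total,4,-0.3657,0.6343,-0.6484,8.9781,0.1337,0.6343
age_range,18-<35,A,4,0.7128,0.2872,7.8113,7.5195,0.5081,0.2872
age_range,18-<35,B,4,-0.4333,0.5667,-3.7724,9.1134,0.1877,0.5667
age_range,18-<35,C,4,-0.7383,0.2617,-8.1068,9.2192,0.5451,0.2617
age_range,18-<35,D,4,-0.4348,0.5652,-1.4655,8.9847,0.1890,0.5652
age_range,18-<35,E,4,-0.6512,0.3488,-9.7694,9.0226,0.4240,0.3488
highest_degree,high_school,total,4,-0.8858,0.1142,-2.9904,11.7516,0.7847,0.1142
highest_degree,high_school,A,4,0.5025,0.4975,6.1810,7.8185,0.2525,0.4975
highest_degree,high_school,B,4,-0.5653,0.4347,-5.3240,9.5916,0.3196,0.4347
highest_degree,high_school,C,4,-0.9737,0.0263,-12.7256,9.9739,0.9481,0.0263
highest_degree,high_school,D,4,-0.9999,0.0001,-6.6848,11.9035,0.9999,0.0001
highest_degree,high_school,E,4,-0.5587,0.4413,-8.7997,9.3196,0.3121,0.4413
employment,in_education,total,3,-0.4965,0.6692,-0.5486,8.7440,0.2465,0.6692
employment,in_education,A,3,-0.7274,0.4815,-14.3351,8.9698,0.5291,0.4815
employment,in_education,B,3,-0.8335,0.3727,-4.6085,9.2112,0.6947,0.3727
employment,in_education,C,3,-0.7421,0.4677,-5.5450,8.8269,0.5507,0.4677
employment,in_education,D,3,-0.3643,0.7626,-0.8194,8.5805,0.1327,0.7626
employment,in_education,E,3,-0.2018,0.8706,-1.9628,8.4532,0.0407,0.8706
use_type,mainly_private,total,6,-0.3269,0.5271,-0.6202,8.9756,0.1068,0.5271
use_type,mainly_private,A,6,0.1878,0.7216,1.4414,8.2326,0.0353,0.7216
use_type,mainly_private,B,6,-0.5061,0.3057,-4.3658,9.2717,0.2561,0.3057
use_type,mainly_private,C,6,-0.7600,0.0795,-8.6100,9.3020,0.5775,0.0795
use_type,mainly_private,D,6,-0.1784,0.7353,-0.5246,8.6006,0.0318,0.7353
use_type,mainly_private,E,6,-0.4306,0.3941,-5.9285,8.8966,0.1854,0.3941
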