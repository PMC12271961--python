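variable,grouping,level,n,median,q1,q3,shapiro_p,levene_W,levene_p,H,df,p_value
mean_total_hours,gender,female,4,0.9991,0.9069,1.1728,0.2598,0.4649,0.5328,3.4286,1,0.0641
mean_total_hours,gender,male,2,0.5883,0.4535,0.7230,,0.4649,0.5328,3.4286,1,0.0641
mean_total_hours,age_range,18-<35,4,0.9848,0.7437,1.1728,0.8975,2.0664,0.2239,0.2143,1,0.6434
mean_total_hours,age_range,35-<60,2,0.8859,0.8719,0.9000,,2.0664,0.2239,0.2143,1,0.6434
mean_total_hours,highest_degree,bachelor,2,0.5883,0.4535,0.7230,,0.4649,0.5328,3.4286,1,0.0641
mean_total_hours,highest_degree,high_school,4,0.9991,0.9069,1.1728,0.2598,0.4649,0.5328,3.4286,1,0.0641
mean_total_hours,employment,in_education,3,0.9141,0.6164,1.1766,0.9308,,,1.2381,2,0.5385
mean_total_hours,employment,part_time,1,1.0841,1.0841,1.0841,,,,1.2381,2,0.5385
mean_total_hours,employment,full_time,2,0.8716,0.8647,0.8785,,,,1.2381,2,0.5385
mean_hours_A,gender,female,4,0.1041,0.0738,0.1438,0.8783,4.3076,0.1066,0.0000,1,1.0000
mean_hours_A,gender,male,2,0.1363,0.0802,0.1924,,4.3076,0.1066,0.0000,1,1.0000
mean_hours_A,age_range,18-<35,4,0.1041,0.0697,0.1438,0.9716,2.4262,0.1943,0.2143,1,0.6434
mean_hours_A,age_range,35-<60,2,0.1445,0.0925,0.1965,,2.4262,0.1943,0.2143,1,0.6434
mean_hours_A,highest_degree,bachelor,2,0.1363,0.0802,0.1924,,4.3076,0.1066,0.0000,1,1.0000
mean_hours_A,highest_degree,high_school,4,0.1041,0.0738,0.1438,0.8783,4.3076,0.1066,0.0000,1,1.0000
mean_hours_A,employment,in_education,3,0.0406,0.0323,0.0627,0.5060,,,4.2857,2,0.1173
mean_hours_A,employment,part_time,1,0.1234,0.1234,0.1234,,,,4.2857,2,0.1173
mean_hours_A,employment,full_time,2,0.2268,0.2160,0.2377,,,,4.2857,2,0.1173
mean_hours_B,gender,female,4,0.1650,0.1499,0.2163,0.0670,0.0048,0.9483,0.2143,1,0.6434
mean_hours_B,gender,male,2,0.1915,0.1620,0.2210,,0.0048,0.9483,0.2143,1,0.6434
mean_hours_B,age_range,18-<35,4,0.1577,0.1374,0.2163,0.0744,0.0395,0.8522,0.2143,1,0.6434
mean_hours_B,age_range,35-<60,2,0.2020,0.1778,0.2263,,0.0395,0.8522,0.2143,1,0.6434
mean_hours_B,highest_degree,bachelor,2,0.1915,0.1620,0.2210,,0.0048,0.9483,0.2143,1,0.6434
mean_hours_B,highest_degree,high_school,4,0.1650,0.1499,0.2163,0.0670,0.0048,0.9483,0.2143,1,0.6434
mean_hours_B,employment,in_education,3,0.1535,0.1430,0.2449,0.1796,,,1.2381,2,0.5385
mean_hours_B,employment,part_time,1,0.1390,0.1390,0.1390,,,,1.2381,2,0.5385
mean_hours_B,employment,full_time,2,0.2135,0.1949,0.2320,,,,1.2381,2,0.5385
mean_hours_C,gender,female,4,0.1065,0.0695,0.1513,0.7818,0.0620,0.8157,0.8571,1,0.3545
mean_hours_C,gender,male,2,0.0833,0.0600,0.1066,,0.0620,0.8157,0.8571,1,0.3545
mean_hours_C,age_range,18-<35,4,0.0922,0.0452,0.1513,0.4213,2.7385,0.1733,0.0000,1,1.0000
mean_hours_C,age_range,35-<60,2,0.1033,0.0899,0.1166,,2.7385,0.1733,0.0000,1,1.0000
mean_hours_C,highest_degree,bachelor,2,0.0833,0.0600,0.1066,,0.0620,0.8157,0.8571,1,0.3545
mean_hours_C,highest_degree,high_school,4,0.1065,0.0695,0.1513,0.7818,0.0620,0.8157,0.8571,1,0.3545
mean_hours_C,employment,in_education,3,0.0766,0.0566,0.1363,0.4646,,,0.8095,2,0.6671
mean_hours_C,employment,part_time,1,0.1364,0.1364,0.1364,,,,0.8095,2,0.6671
mean_hours_C,employment,full_time,2,0.0890,0.0685,0.1094,,,,0.8095,2,0.6671
mean_hours_D,gender,female,4,0.5173,0.4289,0.5945,0.7818,7.0859,0.0563,3.4286,1,0.0641
mean_hours_D,gender,male,2,0.0942,0.0927,0.0957,,7.0859,0.0563,3.4286,1,0.0641
mean_hours_D,age_range,18-<35,4,0.4657,0.2879,0.5945,0.5537,0.0141,0.9112,0.8571,1,0.3545
mean_hours_D,age_range,35-<60,2,0.2729,0.1821,0.3638,,0.0141,0.9112,0.8571,1,0.3545
mean_hours_D,highest_degree,bachelor,2,0.0942,0.0927,0.0957,,7.0859,0.0563,3.4286,1,0.0641
mean_hours_D,highest_degree,high_school,4,0.5173,0.4289,0.5945,0.7818,7.0859,0.0563,3.4286,1,0.0641
mean_hours_D,employment,in_education,3,0.4547,0.2759,0.5466,0.6505,,,2.1429,2,0.3425
mean_hours_D,employment,part_time,1,0.5799,0.5799,0.5799,,,,2.1429,2,0.3425
mean_hours_D,employment,full_time,2,0.2213,0.1563,0.2864,,,,2.1429,2,0.3425
mean_hours_E,gender,female,4,0.0901,0.0494,0.1316,0.3986,0.9354,0.3882,0.8571,1,0.3545
mean_hours_E,gender,male,2,0.0660,0.0472,0.0848,,0.9354,0.3882,0.8571,1,0.3545
mean_hours_E,age_range,18-<35,4,0.0447,0.0336,0.0775,0.0858,0.4589,0.5353,0.8571,1,0.3545
mean_hours_E,age_range,35-<60,2,0.1149,0.1093,0.1205,,0.4589,0.5353,0.8571,1,0.3545
mean_hours_E,highest_degree,bachelor,2,0.0660,0.0472,0.0848,,0.9354,0.3882,0.8571,1,0.3545
mean_hours_E,highest_degree,high_school,4,0.0901,0.0494,0.1316,0.3986,0.9354,0.3882,0.8571,1,0.3545
mean_hours_E,employment,in_education,3,0.1262,0.0773,0.1370,0.3265,,,0.4286,2,0.8071
mean_hours_E,employment,part_time,1,0.0541,0.0541,0.0541,,,,0.4286,2,0.8071
mean_hours_E,employment,full_time,2,0.0695,0.0524,0.0865,,,,0.4286,2,0.8071
mean_gap_hours,gender,female,4,8.4515,7.9362,9.0352,0.8068,5.4289,0.0803,0.0000,1,1.0000
mean_gap_hours,gender,male,2,8.1814,8.1329,8.2299,,5.4289,0.0803,0.0000,1,1.0000
mean_gap_hours,age_range,18-<35,4,8.1592,7.9362,8.5969,0.4266,0.1142,0.7524,0.2143,1,0.6434
mean_gap_hours,age_range,35-<60,2,8.4736,8.2790,8.6683,,0.1142,0.7524,0.2143,1,0.6434
mean_gap_hours,highest_degree,bachelor,2,8.1814,8.1329,8.2299,,5.4289,0.0803,0.0000,1,1.0000
mean_gap_hours,highest_degree,high_school,4,8.4515,7.9362,9.0352,0.8068,5.4289,0.0803,0.0000,1,1.0000
mean_gap_hours,employment,in_education,3,8.2784,7.9516,8.5706,0.9385,,,1.2381,2,0.5385
mean_gap_hours,employment,part_time,1,8.0401,8.0401,8.0401,,,,1.2381,2,0.5385
mean_gap_hours,employment,full_time,2,8.8183,8.4514,9.1853,,,,1.2381,2,0.5385
prop_adequate,gender,female,4,0.9000,0.7000,1.0000,0.1612,0.4444,0.5415,0.0625,1,0.8026
prop_adequate,gender,male,2,0.9000,0.8500,0.9500,,0.4444,0.5415,0.0625,1,0.8026
prop_adequate,age_range,18-<35,4,0.8000,0.7000,0.8500,0.4064,1.0909,0.3552,2.2500,1,0.1336
prop_adequate,age_range,35-<60,2,1.0000,1.0000,1.0000,,1.0909,0.3552,2.2500,1,0.1336
prop_adequate,highest_degree,bachelor,2,0.9000,0.8500,0.9500,,0.4444,0.5415,0.0625,1,0.8026
prop_adequate,highest_degree,high_school,4,0.9000,0.7000,1.0000,0.1612,0.4444,0.5415,0.0625,1,0.8026
prop_adequate,employment,in_education,3,0.8000,0.6000,0.9000,0.6369,,,2.2778,2,0.3202
prop_adequate,employment,part_time,1,0.8000,0.8000,0.8000,,,,2.2778,2,0.3202
prop_adequate,employment,full_time,2,1.0000,1.0000,1.0000,,,,2.2778,2,0.3202
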