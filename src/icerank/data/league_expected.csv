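scheme,arm_id,effect,effect_lower,effect_upper,std_cost,std_rank,std_icer,std_icer_lower,std_icer_upper,local_cost,local_rank,local_icer,local_icer_lower,local_icer_upper
averaged,aboud_2013_home,0.83,0.65,1.03,24,1,29,23,37,1,1,1,1,2
averaged,aboud_2013_group,0.83,0.65,1.03,41,2,49,40,63,6,2,7,6,9
averaged,nair_2009,0.21,0.06,0.35,18,3,86,51,300,5,3,24,14,83
averaged,jin_2007,0.50,0.07,0.92,62,4,125,67,886,17,4,34,18,243
averaged,yousafzai_2014,0.65,0.45,0.76,134,5,206,177,298,134,7,206,177,298
averaged,aboud_akhter_2011,0.40,0.10,0.69,99,6,248,143,990,69,6,172,100,690
averaged,eickmann_2003,0.81,0.46,1.16,228,7,281,197,496,252,8,311,217,548
averaged,nahar_2009,0.84,0.35,1.33,582,8,693,438,1663,101,5,120,76,289
averaged,vazir_2013,0.36,0.14,0.57,418,9,1161,733,2986,147,9,408,258,1050
averaged,powell_2004,0.78,0.54,1.14,1290,10,1647,1128,2374,781,11,997,683,1437
averaged,hamadani_2006,0.33,0.04,0.61,1357,11,4112,2225,33925,183,10,555,300,4575
averaged,lozoff_2010,0.70,0.20,1.09,3519,12,5063,3228,18046,2172,12,3125,1993,11138
summed,aboud_2013_home,2.49,1.94,3.10,24,1,10,8,12,1,1,0,0,1
summed,aboud_2013_group,2.49,1.94,3.10,41,2,16,13,21,6,2,2,2,3
summed,jin_2007,0.99,0.14,1.85,62,3,63,34,443,17,3,17,9,121
summed,nair_2009,0.21,0.06,0.35,18,4,86,51,300,5,4,24,14,83
summed,yousafzai_2014,1.30,0.90,1.51,134,5,103,89,149,134,5,103,89,149
summed,aboud_akhter_2011,0.40,0.10,0.69,99,6,248,143,990,69,7,172,100,690
summed,eickmann_2003,0.81,0.46,1.16,228,7,281,197,496,252,8,311,217,548
summed,powell_2004,2.35,1.63,3.43,1290,8,549,376,791,781,9,332,228,479
summed,nahar_2009,0.84,0.35,1.33,582,9,693,438,1663,101,6,120,76,289
summed,vazir_2013,0.36,0.14,0.57,418,10,1161,733,2986,147,10,408,258,1050
summed,lozoff_2010,1.39,0.39,2.18,3519,11,2532,1614,9023,2172,12,1563,996,5569
summed,hamadani_2006,0.33,0.04,0.61,1357,12,4112,2225,33925,183,11,555,300,4575
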