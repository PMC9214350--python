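arm_id,study_label,country,study_year,year_imputed,total_cost,per_child_local,per_child_standardized,league_eligible,domain,subgroup,estimate,lower,upper,significant
aboud_akhter_2011,"Aboud and Akhter, 2011",Bangladesh,2008,False,13151,69,99,True,cognitive,,0.40,0.10,0.69,True
aboud_2013_group,"Aboud et al, 2013 (Group sessions)",Bangladesh,2011,False,,6,41,True,cognitive,,0.67,0.48,0.86,True
aboud_2013_group,"Aboud et al, 2013 (Group sessions)",Bangladesh,2011,False,,6,41,True,expressive_language,,0.97,0.82,1.21,True
aboud_2013_group,"Aboud et al, 2013 (Group sessions)",Bangladesh,2011,False,,6,41,True,receptive_language,,0.85,0.64,1.03,True
aboud_2013_home,"Aboud et al, 2013 (Home visits)",Bangladesh,2011,False,,1,24,True,cognitive,,0.67,0.48,0.86,True
aboud_2013_home,"Aboud et al, 2013 (Home visits)",Bangladesh,2011,False,,1,24,True,expressive_language,,0.97,0.82,1.21,True
aboud_2013_home,"Aboud et al, 2013 (Home visits)",Bangladesh,2011,False,,1,24,True,receptive_language,,0.85,0.64,1.03,True
boivin_2013,"Boivin et al, 2013",Uganda,2012,True,39617,660,992,False,cognitive,,0.03,-0.33,0.40,False
boivin_2013,"Boivin et al, 2013",Uganda,2012,True,39617,660,992,False,expressive_language,,0.39,0.02,0.75,True
boivin_2013,"Boivin et al, 2013",Uganda,2012,True,39617,660,992,False,fine_motor,,0.11,-0.25,0.47,False
boivin_2013,"Boivin et al, 2013",Uganda,2012,True,39617,660,992,False,receptive_language,,0.44,0.07,0.81,True
carlo_2003,"Carlo et al, 2003","India, Pakistan, Zambia",2007,False,20487,347,1256,False,cognitive,non-resuscitated,0.23,-0.07,0.53,False
carlo_2003,"Carlo et al, 2003","India, Pakistan, Zambia",2007,False,20487,347,1256,False,cognitive,resuscitated,0.37,0.01,0.72,True
eickmann_2003,"Eickmann et al, 2003",Brazil,1999,False,16636,252,228,True,cognitive,,0.81,0.46,1.16,True
gardner_2005,"Gardner et al, 2005",Jamaica,2004,True,38333,782,1282,False,cognitive,,0.32,-0.05,0.70,False
gardner_2005,"Gardner et al, 2005",Jamaica,2004,True,38333,782,1282,False,fine_motor,,0.16,-0.22,0.53,False
gardner_2005,"Gardner et al, 2005",Jamaica,2004,True,38333,782,1282,False,language,,0.55,0.16,0.93,True
hamadani_2006,"Hamadani et al, 2006",Bangladesh,2000,False,16801,183,1357,True,cognitive,,0.33,0.04,0.61,True
jin_2007,"Jin et al, 2007",China,2003,False,828,17,62,True,cognitive,,0.48,0.06,0.91,True
jin_2007,"Jin et al, 2007",China,2003,False,828,17,62,True,language,,0.51,0.08,0.94,True
lozoff_2010,"Lozoff et al, 2010",Chile,1991,False,167228,2172,3519,True,cognitive,iron-deficient,1.80,1.21,2.18,True
lozoff_2010,"Lozoff et al, 2010",Chile,1991,False,167228,2172,3519,True,cognitive,non-iron-deficient,-0.41,-0.82,0.00,False
nahar_2009,"Nahar et al, 2009",Bangladesh,2008,True,3324,101,582,True,cognitive,,0.84,0.35,1.33,True
nair_2009,"Nair et al, 2009",India,2008,True,1690,5,18,True,cognitive,,0.21,0.06,0.35,True
powell_2004,"Powell et al, 2004",Jamaica,2003,True,50753,781,1290,True,cognitive,,0.87,0.87,1.23,True
powell_2004,"Powell et al, 2004",Jamaica,2003,True,50753,781,1290,True,fine_motor,,0.71,0.35,1.07,True
powell_2004,"Powell et al, 2004",Jamaica,2003,True,50753,781,1290,True,language,,0.77,0.41,1.13,True
vazir_2013,"Vazir et al, 2013",India,2012,True,22534,147,418,True,cognitive,,0.36,0.14,0.57,True
walker_2004,"Walker et al, 2004",Jamaica,2003,True,28218,448,735,False,cognitive,,0.42,0.07,0.77,True
walker_2004,"Walker et al, 2004",Jamaica,2003,True,28218,448,735,False,language,,0.00,-0.34,0.34,False
yousafzai_2014,"Yousafzai et al, 2014",Pakistan,2009,False,48816,134,134,True,cognitive,,0.60,0.45,0.76,True
yousafzai_2014,"Yousafzai et al, 2014",Pakistan,2009,False,48816,134,134,True,language,,0.70,0.45,0.75,True
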