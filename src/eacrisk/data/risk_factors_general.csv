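factor,level,rr,ci_low,ci_high,prevalence,is_reference
sGERD,rarely,1.0,1.0,1.0,0.55,1
sGERD,less_than_weekly,1.8,1.4,2.3,0.25,0
sGERD,weekly_daily,4.5,3.5,5.8,0.15,0
sGERD,daily_plus,6.5,4.8,8.8,0.05,0
bmi,normal,1.0,1.0,1.0,0.35,1
bmi,overweight,1.5,1.2,1.9,0.4,0
bmi,obese_1,2.0,1.5,2.7,0.15,0
bmi,obese_2_plus,2.6,1.8,3.8,0.1,0
smoking,never,1.0,1.0,1.0,0.5,1
smoking,former,1.6,1.3,2.0,0.35,0
smoking,current,2.3,1.8,2.9,0.15,0
family_history,none,1.0,1.0,1.0,0.96,1
family_history,first_degree,3.0,1.8,5.0,0.04,0
physical_activity,low,1.0,1.0,1.0,0.35,1
physical_activity,moderate,0.8,0.66,0.97,0.45,0
physical_activity,high,0.68,0.52,0.89,0.2,0
NSAID,nonuser,1.0,1.0,1.0,0.6,1
NSAID,user,0.68,0.56,0.83,0.4,0
statin,nonuser,1.0,1.0,1.0,0.67,1
statin,user,0.57,0.43,0.75,0.33,0
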