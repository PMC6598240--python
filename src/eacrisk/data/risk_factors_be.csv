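factor,level,rr,ci_low,ci_high,prevalence,is_reference
segment_length,lt_3cm,1.0,1.0,1.0,0.45,1
segment_length,3_to_6cm,1.8,1.2,2.7,0.35,0
segment_length,gt_6cm,3.5,2.0,6.1,0.2,0
dysplasia,none,1.0,1.0,1.0,0.8,1
dysplasia,indefinite,2.5,1.4,4.4,0.1,0
dysplasia,low_grade_confirmed,5.0,2.8,9.0,0.08,0
dysplasia,high_grade,10.0,5.0,20.0,0.02,0
sGERD,rarely,1.0,1.0,1.0,0.55,1
sGERD,less_than_weekly,1.342,1.183,1.517,0.25,0
sGERD,weekly_daily,2.121,1.871,2.408,0.15,0
sGERD,daily_plus,2.55,2.191,2.966,0.05,0
smoking,never,1.0,1.0,1.0,0.45,1
smoking,ever,1.5,1.1,2.0,0.55,0
bmi,normal,1.0,1.0,1.0,0.3,1
bmi,overweight_obese,1.2,0.9,1.6,0.7,0
NSAID,nonuser,1.0,1.0,1.0,0.55,1
NSAID,user,0.6,0.45,0.8,0.45,0
statin,nonuser,1.0,1.0,1.0,0.6,1
statin,user,0.57,0.43,0.75,0.4,0
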