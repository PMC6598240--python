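sex,race,age_lo,age_hi,rate
male,white,40,44,3.66158e-05
male,white,45,49,4.82058e-05
male,white,50,54,6.34645e-05
male,white,55,59,8.35529e-05
male,white,60,64,0.00011
male,white,65,69,0.000144818
male,white,70,74,0.000190658
male,white,75,79,0.000251007
male,white,80,84,0.000330458
male,white,85,89,0.000435058
female,white,40,44,5.32594e-06
female,white,45,49,7.01176e-06
female,white,50,54,9.2312e-06
female,white,55,59,1.21532e-05
female,white,60,64,1.6e-05
female,white,65,69,2.10645e-05
female,white,70,74,2.7732e-05
female,white,75,79,3.65101e-05
female,white,80,84,4.80667e-05
female,white,85,89,6.32812e-05
male,black,40,44,9.93274e-06
male,black,45,49,1.27539e-05
male,black,50,54,1.63763e-05
male,black,55,59,2.10276e-05
male,black,60,64,2.7e-05
male,black,65,69,3.46687e-05
male,black,70,74,4.45155e-05
male,black,75,79,5.7159e-05
male,black,80,84,7.33936e-05
male,black,85,89,9.42393e-05
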