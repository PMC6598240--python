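sex,race,age_lo,age_hi,rate
male,white,40,44,0.00239598
male,white,45,49,0.00366486
male,white,50,54,0.00560574
male,white,55,59,0.00857448
male,white,60,64,0.0131154
male,white,65,69,0.0200613
male,white,70,74,0.0306855
male,white,75,79,0.0469363
male,white,80,84,0.0717933
male,white,85,89,0.109814
female,white,40,44,0.00143759
female,white,45,49,0.00219892
female,white,50,54,0.00336344
female,white,55,59,0.00514469
female,white,60,64,0.00786927
female,white,65,69,0.0120368
female,white,70,74,0.0184113
female,white,75,79,0.0281618
female,white,80,84,0.043076
female,white,85,89,0.0658886
male,black,40,44,0.00316269
male,black,45,49,0.00483762
male,black,50,54,0.00739957
male,black,55,59,0.0113183
male,black,60,64,0.0173124
male,black,65,69,0.0264809
male,black,70,74,0.0405049
male,black,75,79,0.0619559
male,black,80,84,0.0947671
male,black,85,89,0.144955
female,black,40,44,0.00182094
female,black,45,49,0.0027853
female,black,50,54,0.00426036
female,black,55,59,0.00651661
female,black,60,64,0.00996774
female,black,65,69,0.0152466
female,black,70,74,0.023321
female,black,75,79,0.0356716
female,black,80,84,0.0545629
female,black,85,89,0.0834589
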