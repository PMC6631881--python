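sex,age_start,age_width,mmhg_per_gram
male,15,5,1.0
male,20,5,1.0
male,25,5,1.0
male,30,5,1.0
male,35,5,1.0
male,40,5,1.0
male,45,5,1.0
male,50,5,1.0
male,55,5,1.0
male,60,5,1.0
male,65,5,1.0
male,70,5,1.0
male,75,5,1.0
male,80,5,1.0
male,85,5,1.0
male,90,5,1.0
male,95,5,1.0
female,15,5,0.889
female,20,5,0.889
female,25,5,0.889
female,30,5,0.889
female,35,5,0.889
female,40,5,0.889
female,45,5,0.889
female,50,5,0.889
female,55,5,0.889
female,60,5,0.889
female,65,5,0.889
female,70,5,0.889
female,75,5,0.889
female,80,5,0.889
female,85,5,0.889
female,90,5,0.889
female,95,5,0.889
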