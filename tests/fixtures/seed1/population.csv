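sex,age_start,age_width,count
male,15,5,1800000.0
male,20,5,1800000.0
male,25,5,1800000.0
male,30,5,1800000.0
male,35,5,1800000.0
male,40,5,1800000.0
male,45,5,1596456.7860908834
male,50,5,1182684.275667102
male,55,5,876154.060727949
male,60,5,649070.8923115409
male,65,5,480843.5435385307
male,70,5,356217.6583505065
male,75,5,263892.5318346303
male,80,5,195496.39588492442
male,85,5,144827.29214915837
male,90,5,107290.69687609085
male,95,5,79482.90315544714
female,15,5,1800000.0
female,20,5,1800000.0
female,25,5,1800000.0
female,30,5,1800000.0
female,35,5,1800000.0
female,40,5,1800000.0
female,45,5,1596456.7860908834
female,50,5,1182684.275667102
female,55,5,876154.060727949
female,60,5,649070.8923115409
female,65,5,480843.5435385307
female,70,5,356217.6583505065
female,75,5,263892.5318346303
female,80,5,195496.39588492442
female,85,5,144827.29214915837
female,90,5,107290.69687609085
female,95,5,79482.90315544714
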