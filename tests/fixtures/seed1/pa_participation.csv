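sex,age_start,age_width,participation
male,15,5,0.11491041692261786
male,20,5,0.10397524495369719
male,25,5,0.0940806921835598
male,30,5,0.08512773060240812
male,35,5,0.07702675596154371
male,40,5,0.06969669098392917
male,45,5,0.06306417391554861
male,50,5,0.05706282429631572
male,55,5,0.05163257860211794
male,60,5,0.046719089108879126
male,65,5,0.042273179962270105
male,70,5,0.03825035500922994
male,75,5,0.034610352465510454
male,80,5,0.03131674196220699
male,85,5,0.028336559938381765
male,90,5,0.025639979730666566
male,95,5,0.023200013057990673
female,15,5,0.13489483725698617
female,20,5,0.12205789624999236
female,25,5,0.1104425516937441
female,30,5,0.0999325533158704
female,35,5,0.09042271352007304
female,40,5,0.08181785463330815
female,45,5,0.07403185633564402
female,50,5,0.06698679373915324
female,55,5,0.0606121574894428
female,60,5,0.05484414808433637
female,65,5,0.049625037347012735
female,70,5,0.044902590663009063
female,75,5,0.04062954419864271
female,80,5,0.03676313186867777
female,85,5,0.0332646573189699
female,90,5,0.030099106640347706
female,95,5,0.027234797937641223
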