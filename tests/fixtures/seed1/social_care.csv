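sex,age_start,age_width,eligibility,base_monthly_cost,utility_sensitivity
male,15,5,6.324273266387667e-08,2700.0,2.0
male,20,5,1.921144036920684e-07,2700.0,2.0
male,25,5,5.835915213186115e-07,2700.0,2.0
male,30,5,1.772789824494969e-06,2700.0,2.0
male,35,5,5.385216753761719e-06,2700.0,2.0
male,40,5,1.6358445147320682e-05,2700.0,2.0
male,45,5,4.96888879091782e-05,2700.0,2.0
male,50,5,0.00015090755870991515,2700.0,2.0
male,55,5,0.00045810363978128444,2700.0,2.0
male,60,5,0.0013887151950648356,2700.0,2.0
male,65,5,0.0041921817052800086,2700.0,2.0
male,70,5,0.012497478617786393,2700.0,2.0
male,75,5,0.035930594976576406,2700.0,2.0
male,80,5,0.09387383729672023,2700.0,2.0
male,85,5,0.200102375131934,2700.0,2.0
male,90,5,0.318897371263246,2700.0,2.0
male,95,5,0.39635868509004707,2700.0,2.0
female,15,5,6.324273266387667e-08,2700.0,2.0
female,20,5,1.921144036920684e-07,2700.0,2.0
female,25,5,5.835915213186115e-07,2700.0,2.0
female,30,5,1.772789824494969e-06,2700.0,2.0
female,35,5,5.385216753761719e-06,2700.0,2.0
female,40,5,1.6358445147320682e-05,2700.0,2.0
female,45,5,4.96888879091782e-05,2700.0,2.0
female,50,5,0.00015090755870991515,2700.0,2.0
female,55,5,0.00045810363978128444,2700.0,2.0
female,60,5,0.0013887151950648356,2700.0,2.0
female,65,5,0.0041921817052800086,2700.0,2.0
female,70,5,0.012497478617786393,2700.0,2.0
female,75,5,0.035930594976576406,2700.0,2.0
female,80,5,0.09387383729672023,2700.0,2.0
female,85,5,0.200102375131934,2700.0,2.0
female,90,5,0.318897371263246,2700.0,2.0
female,95,5,0.39635868509004707,2700.0,2.0
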