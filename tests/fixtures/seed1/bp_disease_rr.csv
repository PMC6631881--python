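disease,sex,age_start,age_width,rr_per_mmhg
ihd,male,15,5,1.0294878048780487
ihd,male,20,5,1.0282073170731707
ihd,male,25,5,1.0269268292682927
ihd,male,30,5,1.0256463414634147
ihd,male,35,5,1.0243658536585365
ihd,male,40,5,1.0230853658536585
ihd,male,45,5,1.0218048780487805
ihd,male,50,5,1.0205243902439025
ihd,male,55,5,1.0192439024390243
ihd,male,60,5,1.0179634146341463
ihd,male,65,5,1.0166829268292683
ihd,male,70,5,1.0154024390243903
ihd,male,75,5,1.014121951219512
ihd,male,80,5,1.012841463414634
ihd,male,85,5,1.011560975609756
ihd,male,90,5,1.0102804878048781
ihd,male,95,5,1.009
ihd,female,15,5,1.0294878048780487
ihd,female,20,5,1.0282073170731707
ihd,female,25,5,1.0269268292682927
ihd,female,30,5,1.0256463414634147
ihd,female,35,5,1.0243658536585365
ihd,female,40,5,1.0230853658536585
ihd,female,45,5,1.0218048780487805
ihd,female,50,5,1.0205243902439025
ihd,female,55,5,1.0192439024390243
ihd,female,60,5,1.0179634146341463
ihd,female,65,5,1.0166829268292683
ihd,female,70,5,1.0154024390243903
ihd,female,75,5,1.014121951219512
ihd,female,80,5,1.012841463414634
ihd,female,85,5,1.011560975609756
ihd,female,90,5,1.0102804878048781
ihd,female,95,5,1.009
stroke,male,15,5,1.0393170731707317
stroke,male,20,5,1.037609756097561
stroke,male,25,5,1.0359024390243903
stroke,male,30,5,1.0341951219512195
stroke,male,35,5,1.0324878048780488
stroke,male,40,5,1.030780487804878
stroke,male,45,5,1.0290731707317073
stroke,male,50,5,1.0273658536585366
stroke,male,55,5,1.0256585365853659
stroke,male,60,5,1.0239512195121951
stroke,male,65,5,1.0222439024390244
stroke,male,70,5,1.0205365853658537
stroke,male,75,5,1.018829268292683
stroke,male,80,5,1.0171219512195122
stroke,male,85,5,1.0154146341463415
stroke,male,90,5,1.0137073170731707
stroke,male,95,5,1.012
stroke,female,15,5,1.0393170731707317
stroke,female,20,5,1.037609756097561
stroke,female,25,5,1.0359024390243903
stroke,female,30,5,1.0341951219512195
stroke,female,35,5,1.0324878048780488
stroke,female,40,5,1.030780487804878
stroke,female,45,5,1.0290731707317073
stroke,female,50,5,1.0273658536585366
stroke,female,55,5,1.0256585365853659
stroke,female,60,5,1.0239512195121951
stroke,female,65,5,1.0222439024390244
stroke,female,70,5,1.0205365853658537
stroke,female,75,5,1.018829268292683
stroke,female,80,5,1.0171219512195122
stroke,female,85,5,1.0154146341463415
stroke,female,90,5,1.0137073170731707
stroke,female,95,5,1.012
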