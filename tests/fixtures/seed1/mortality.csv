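sex,age_start,age_width,all_cause_mortality
male,15,5,0.0002844731643168877
male,20,5,0.0004351274267904376
male,25,5,0.0006655667433514314
male,30,5,0.0010180445142769045
male,35,5,0.001557191135828811
male,40,5,0.002381864642948485
male,45,5,0.003643277338788936
male,50,5,0.005572722113588245
male,55,5,0.008523982356390836
male,60,5,0.013038201749715093
male,65,5,0.019943108486002503
male,70,5,0.03050478767849688
male,75,5,0.046659830986894295
male,80,5,0.07137043046066595
male,85,5,0.109167526679886
male,90,5,0.16698160294790004
male,95,5,0.25541346012914207
female,15,5,0.0002370609702640731
female,20,5,0.00036260618899203135
female,25,5,0.0005546389527928596
female,30,5,0.0008483704285640871
female,35,5,0.0012976592798573424
female,40,5,0.001984887202457071
female,45,5,0.00303606444899078
female,50,5,0.004643935094656871
female,55,5,0.007103318630325697
female,60,5,0.010865168124762578
female,65,5,0.016619257071668753
female,70,5,0.0254206563987474
female,75,5,0.03888319248907858
female,80,5,0.05947535871722163
female,85,5,0.090972938899905
female,90,5,0.1391513357899167
female,95,5,0.2128445501076184
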