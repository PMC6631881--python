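sex,age_start,age_width,baseline_utility,background_disability,unrelated_nhs_cost,unrelated_social_cost
male,15,5,0.9343999999999999,0.054400000000000004,375.3778634389758,5.694141916623109
male,20,5,0.9204,0.0654,447.1674596217103,7.880866915169956
male,25,5,0.9064,0.0764,532.6865444665218,10.907361327491005
male,30,5,0.8924,0.0874,634.5608307360549,15.096122344032842
male,35,5,0.8784,0.09840000000000002,755.9181888247203,20.893495959616235
male,40,5,0.8644,0.1094,900.4846825059141,28.917238709783874
male,45,5,0.8503999999999999,0.12040000000000001,1072.698971152551,40.02234457148177
male,50,5,0.8363999999999999,0.13140000000000002,1277.8485909494455,55.392151410932144
male,55,5,0.8223999999999999,0.14240000000000003,1522.2322993719597,76.66443509953598
male,60,5,0.8084,0.1534,1813.3534674319774,106.10592763456019
male,65,5,0.7944,0.1644,2160.150457459244,146.85385556644715
male,70,5,0.7804,0.1754,2573.271059761779,203.2502365843939
male,75,5,0.7664,0.1864,3065.3994142592933,281.30455623563927
male,80,5,0.7524,0.19740000000000002,3651.645454642121,389.33412668414053
male,85,5,0.7384,0.20840000000000003,4350.008832252142,538.8503628570023
male,90,5,0.7243999999999999,0.21940000000000004,5181.931563650705,745.7854157919393
male,95,5,0.7103999999999999,0.2304,6172.956369943063,1032.1898707815412
female,15,5,0.9343999999999999,0.054400000000000004,375.3778634389758,5.694141916623109
female,20,5,0.9204,0.0654,447.1674596217103,7.880866915169956
female,25,5,0.9064,0.0764,532.6865444665218,10.907361327491005
female,30,5,0.8924,0.0874,634.5608307360549,15.096122344032842
female,35,5,0.8784,0.09840000000000002,755.9181888247203,20.893495959616235
female,40,5,0.8644,0.1094,900.4846825059141,28.917238709783874
female,45,5,0.8503999999999999,0.12040000000000001,1072.698971152551,40.02234457148177
female,50,5,0.8363999999999999,0.13140000000000002,1277.8485909494455,55.392151410932144
female,55,5,0.8223999999999999,0.14240000000000003,1522.2322993719597,76.66443509953598
female,60,5,0.8084,0.1534,1813.3534674319774,106.10592763456019
female,65,5,0.7944,0.1644,2160.150457459244,146.85385556644715
female,70,5,0.7804,0.1754,2573.271059761779,203.2502365843939
female,75,5,0.7664,0.1864,3065.3994142592933,281.30455623563927
female,80,5,0.7524,0.19740000000000002,3651.645454642121,389.33412668414053
female,85,5,0.7384,0.20840000000000003,4350.008832252142,538.8503628570023
female,90,5,0.7243999999999999,0.21940000000000004,5181.931563650705,745.7854157919393
female,95,5,0.7103999999999999,0.2304,6172.956369943063,1032.1898707815412
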