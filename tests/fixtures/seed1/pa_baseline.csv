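sex,age_start,age_width,sedentary,under_active,active,recommended
male,15,5,0.15997999999999998,0.12720599999999999,0.15547399999999997,0.5573400000000001
male,20,5,0.17993,0.12909599999999996,0.15778399999999995,0.53319
male,25,5,0.19988,0.13098599999999996,0.16009399999999996,0.50904
male,30,5,0.21983,0.132876,0.162404,0.48489000000000004
male,35,5,0.23978,0.134766,0.164714,0.46074000000000004
male,40,5,0.25972999999999996,0.13665599999999994,0.16702399999999995,0.4365900000000001
male,45,5,0.27968,0.138546,0.169334,0.4124400000000001
male,50,5,0.29963,0.14043599999999998,0.17164399999999996,0.38829
male,55,5,0.31958,0.14232599999999995,0.17395399999999997,0.36414
male,60,5,0.33953,0.14421599999999998,0.17626399999999998,0.33999000000000007
male,65,5,0.35947999999999997,0.14610599999999996,0.17857399999999995,0.31584000000000007
male,70,5,0.37942999999999993,0.14799600000000002,0.18088400000000002,0.29169000000000006
male,75,5,0.39937999999999996,0.149886,0.183194,0.26754000000000006
male,80,5,0.41933,0.15177599999999997,0.18550399999999997,0.24339000000000008
male,85,5,0.43928,0.15366599999999997,0.18781399999999998,0.21924000000000005
male,90,5,0.4592299999999999,0.15555600000000003,0.19012400000000004,0.19509000000000004
male,95,5,0.47917999999999994,0.157446,0.192434,0.17094000000000006
female,15,5,0.17682,0.155457,0.190003,0.47772000000000003
female,20,5,0.19887000000000002,0.1548495,0.1892605,0.45702000000000004
female,25,5,0.22092,0.154242,0.188518,0.43632000000000004
female,30,5,0.24297,0.15363449999999998,0.18777549999999998,0.41562000000000004
female,35,5,0.26502000000000003,0.15302699999999997,0.18703299999999998,0.39492000000000005
female,40,5,0.28707,0.1524195,0.18629050000000003,0.37422000000000005
female,45,5,0.30912,0.15181199999999995,0.18554799999999996,0.35352000000000006
female,50,5,0.33117,0.15120450000000002,0.18480550000000004,0.33282
female,55,5,0.3532200000000001,0.15059699999999995,0.18406299999999995,0.3121200000000001
female,60,5,0.37527,0.1499895,0.18332050000000003,0.29142
female,65,5,0.39731999999999995,0.14938200000000001,0.18257800000000005,0.27072000000000007
female,70,5,0.41937,0.14877449999999995,0.18183549999999996,0.2500200000000001
female,75,5,0.44142000000000003,0.14816699999999997,0.18109299999999998,0.22932000000000002
female,80,5,0.46347000000000005,0.14755949999999998,0.18035049999999997,0.20862000000000006
female,85,5,0.48552000000000006,0.14695199999999997,0.17960799999999996,0.18792000000000003
female,90,5,0.50757,0.14634450000000002,0.1788655,0.16722000000000004
female,95,5,0.52962,0.14573699999999998,0.17812299999999998,0.14652000000000007
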