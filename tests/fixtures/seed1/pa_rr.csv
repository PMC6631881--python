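disease,sedentary,under_active,active,recommended
breast_cancer,1.15,1.1,1.05,1.0
colorectal_cancer,1.25,1.15,1.08,1.0
ihd,1.45,1.25,1.1,1.0
stroke,1.35,1.2,1.08,1.0
type2_diabetes,1.6,1.35,1.15,1.0
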