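disease,affected_by,utility_decrement,disability_per_prevalent_case
breast_cancer,physical_activity,0.09,0.1
colorectal_cancer,physical_activity,0.095,0.105
ihd,blood_pressure;physical_activity,0.06,0.07
kidney_cancer,none,0.09,0.1
liver_cancer,none,0.13,0.145
liver_cirrhosis,none,0.12,0.135
lung_cancer,none,0.13,0.15
pancreatic_cancer,none,0.14,0.16
stomach_cancer,none,0.11,0.125
stroke,blood_pressure;physical_activity,0.11,0.13
type2_diabetes,physical_activity,0.04,0.049
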