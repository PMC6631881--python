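from_category,sedentary,under_active,active,recommended
sedentary,1.0,0.0,0.0,0.0
under_active,0.0,0.45,0.35,0.2
active,0.0,0.0,0.6,0.4
recommended,0.0,0.0,0.0,1.0
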