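# Energy EAR coefficients, kcal per kg body weight per day, by sex and
# self-reported activity level (Indian Council of Medical Research adult
# values divided by the ICMR reference weights: 60 kg men, 55 kg women).
# Pregnancy adds a flat 390 kcal/day on top of the weight-based EAR.
sex,activity_level,kcal_per_kg
male,sedentary,38.7
male,moderate,45.5
male,heavy,58.2
female,sedentary,34.5
female,moderate,40.6
female,heavy,51.8
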