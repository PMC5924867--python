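# Estimated average requirements (EAR mean and SD) per nutrient and member role.
# kind=normal: requirement ~ Normal(ear_mean, ear_sd); kind=tabulated: PA read
# from the iron interval table (non-pregnant adults, 5% bioavailability).
# Sources: WHO/FAO (vitamin C, thiamin, riboflavin, niacin, B6, folate, B12),
# IOM (calcium; pregnant iron at 23% absorption), IZiNCG (zinc, 25% absorption
# for women / 18% for men).
nutrient,role,kind,ear_mean,ear_sd,source
vit_c_mg,pregnant_woman,normal,40,4.0,WHO/FAO
vit_a_re,pregnant_woman,normal,370,74,WHO/FAO
thiamin_mg,pregnant_woman,normal,1.2,0.1,WHO/FAO
riboflavin_mg,pregnant_woman,normal,1.2,0.1,WHO/FAO
niacin_mg,pregnant_woman,normal,14,2.1,WHO/FAO
vit_b6_mg,pregnant_woman,normal,1.6,0.2,WHO/FAO
folate_ug,pregnant_woman,normal,520,52,WHO/FAO
vit_b12_ug,pregnant_woman,normal,2.2,0.2,WHO/FAO
iron_mg,pregnant_woman,normal,22,2.1,IOM 23% absorption
zinc_mg,pregnant_woman,normal,12,1.5,IZiNCG 25% absorption
calcium_mg,pregnant_woman,normal,800,100,IOM
vit_c_mg,mother_in_law,normal,30,3.0,WHO/FAO
vit_a_re,mother_in_law,normal,270,54,WHO/FAO
thiamin_mg,mother_in_law,normal,0.9,0.1,WHO/FAO
riboflavin_mg,mother_in_law,normal,0.9,0.1,WHO/FAO
niacin_mg,mother_in_law,normal,11,1.7,WHO/FAO
vit_b6_mg,mother_in_law,normal,1.1,0.1,WHO/FAO
folate_ug,mother_in_law,normal,320,32,WHO/FAO
vit_b12_ug,mother_in_law,normal,2,0.2,WHO/FAO
iron_mg,mother_in_law,tabulated,,,IOM-style table 5% absorption
zinc_mg,mother_in_law,normal,7,0.9,IZiNCG 25% absorption
calcium_mg,mother_in_law,normal,800,100,IOM
vit_c_mg,household_head,normal,40,4.0,WHO/FAO
vit_a_re,household_head,normal,300,60,WHO/FAO
thiamin_mg,household_head,normal,1,0.1,WHO/FAO
riboflavin_mg,household_head,normal,1,0.1,WHO/FAO
niacin_mg,household_head,normal,12,1.8,WHO/FAO
vit_b6_mg,household_head,normal,1.1,0.1,WHO/FAO
folate_ug,household_head,normal,320,32,WHO/FAO
vit_b12_ug,household_head,normal,2,0.2,WHO/FAO
iron_mg,household_head,tabulated,,,IOM-style table 5% absorption
zinc_mg,household_head,normal,15,1.9,IZiNCG 18% absorption
calcium_mg,household_head,normal,800,100,IOM
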