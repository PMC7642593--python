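nutrient_id,usda_2015,composite_a,composite_b,composite_c
energy,77,78,127,157
protein,8.7,10,8.9,8.2
carbohydrate,8.4,9.3,9.0,8.3
total_fat,0.9,0.1,6,10
saturated_fat,0.6,0.1,3.9,5.7
cholesterol,7.0,9.3,24,33
calcium,295,367,295,501
magnesium,20,45,23,22
phosphorus,232,215,337,307
potassium,235,309,272,245
sodium,202,399,374,387
zinc,1.1,1.7,1.3,1.1
selenium,6.6,7.8,6.5,8.7
vitamin_a,98,85,130,126
vitamin_e,0,0.1,0.1,0.3
vitamin_d,59.3,61.4,116,133
vitamin_c,0.1,0.1,0.3,0.1
thiamin,0.1,0.2,0.1,0.1
riboflavin,0.3,0.4,0.4,0.3
niacin,0.2,1.6,0.2,0.2
vitamin_b6,0.1,0.2,0.1,0.1
vitamin_b12,0.8,1.1,1.0,1.0
choline,24,30,30,27
vitamin_k,0,0.1,0.9,1
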