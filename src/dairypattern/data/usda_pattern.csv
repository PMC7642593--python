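nutrient_id,amount
energy,2003
protein,91
carbohydrate,256
fiber,31
total_fat,72
saturated_fat,18.7
monounsaturated_fat,26.2
polyunsaturated_fat,22.5
linoleic_acid,19.6
linolenic_acid,2.3
epa,0.07
dha,0.15
stearic_acid,4.65
cholesterol,215
calcium,1274
iron,17
magnesium,352
phosphorus,1717
potassium,3348
sodium,1787
zinc,14
copper,1.4
selenium,110
vitamin_a,898
vitamin_e,10.2
vitamin_d,274
vitamin_c,117
thiamin,1.7
riboflavin,2.1
niacin,24
vitamin_b6,2.3
vitamin_b12,6.8
choline,349
vitamin_k,139
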