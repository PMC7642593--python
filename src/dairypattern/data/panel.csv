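nutrient_id,unit,display_precision,category
energy,kcal,0,macronutrient
protein,g,0,macronutrient
carbohydrate,g,0,macronutrient
fiber,g,0,macronutrient
total_fat,g,0,macronutrient
saturated_fat,g,1,macronutrient
monounsaturated_fat,g,1,macronutrient
polyunsaturated_fat,g,1,macronutrient
linoleic_acid,g,1,macronutrient
linolenic_acid,g,1,macronutrient
epa,g,2,macronutrient
dha,g,2,macronutrient
stearic_acid,g,2,macronutrient
cholesterol,mg,0,macronutrient
calcium,mg,0,mineral
iron,mg,0,mineral
magnesium,mg,0,mineral
phosphorus,mg,0,mineral
potassium,mg,0,mineral
sodium,mg,0,mineral
zinc,mg,0,mineral
copper,mg,1,mineral
selenium,mg,0,mineral
vitamin_a,ug_RAE,0,vitamin
vitamin_e,mg_AT,1,vitamin
vitamin_d,IU,0,vitamin
vitamin_c,mg,0,vitamin
thiamin,mg,1,vitamin
riboflavin,mg,1,vitamin
niacin,mg,0,vitamin
vitamin_b6,mg,1,vitamin
vitamin_b12,mg,1,vitamin
choline,mg,0,vitamin
vitamin_k,mg,0,vitamin
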