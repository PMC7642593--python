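group,nutrient_id,goal_type,value,unit,note
females_19_30,protein,RDA,46,g,
females_19_30,carbohydrate,RDA,130,g,
females_19_30,fiber,AI,28,g,14 g per 1000 kcal at the 2000-kcal level
females_19_30,linoleic_acid,AI,12,g,
females_19_30,linolenic_acid,AI,1.1,g,
females_19_30,calcium,RDA,1000,mg,
females_19_30,iron,RDA,18,mg,
females_19_30,magnesium,RDA,310,mg,
females_19_30,phosphorus,RDA,700,mg,
females_19_30,potassium,AI,4700,mg,2005 DRI value; pre-2019 revision
females_19_30,sodium,UL,2300,mg,
females_19_30,zinc,RDA,8,mg,
females_19_30,copper,RDA,0.9,mg,
females_19_30,selenium,RDA,55,mg,value conventionally in ug; stored in as-printed panel unit
females_19_30,vitamin_a,RDA,700,ug_RAE,
females_19_30,vitamin_e,RDA,15,mg_AT,
females_19_30,vitamin_d,RDA,600,IU,15 ug expressed in IU
females_19_30,vitamin_c,RDA,75,mg,
females_19_30,thiamin,RDA,1.1,mg,
females_19_30,riboflavin,RDA,1.1,mg,
females_19_30,niacin,RDA,14,mg,
females_19_30,vitamin_b6,RDA,1.3,mg,
females_19_30,vitamin_b12,RDA,2.4,mg,value conventionally in ug; stored in as-printed panel unit
females_19_30,choline,AI,425,mg,
females_19_30,vitamin_k,AI,90,mg,value conventionally in ug; stored in as-printed panel unit
males_51_plus,protein,RDA,56,g,
males_51_plus,carbohydrate,RDA,130,g,
males_51_plus,fiber,AI,28,g,14 g per 1000 kcal at the 2000-kcal level
males_51_plus,linoleic_acid,AI,14,g,
males_51_plus,linolenic_acid,AI,1.6,g,
males_51_plus,calcium,RDA,1200,mg,
males_51_plus,iron,RDA,8,mg,
males_51_plus,magnesium,RDA,420,mg,
males_51_plus,phosphorus,RDA,700,mg,
males_51_plus,potassium,AI,4700,mg,2005 DRI value; pre-2019 revision
males_51_plus,sodium,UL,2300,mg,
males_51_plus,zinc,RDA,11,mg,
males_51_plus,copper,RDA,0.9,mg,
males_51_plus,selenium,RDA,55,mg,value conventionally in ug; stored in as-printed panel unit
males_51_plus,vitamin_a,RDA,900,ug_RAE,
males_51_plus,vitamin_e,RDA,15,mg_AT,
males_51_plus,vitamin_d,RDA,600,IU,15 ug expressed in IU
males_51_plus,vitamin_c,RDA,90,mg,
males_51_plus,thiamin,RDA,1.2,mg,
males_51_plus,riboflavin,RDA,1.3,mg,
males_51_plus,niacin,RDA,16,mg,
males_51_plus,vitamin_b6,RDA,1.7,mg,
males_51_plus,vitamin_b12,RDA,2.4,mg,value conventionally in ug; stored in as-printed panel unit
males_51_plus,choline,AI,550,mg,
males_51_plus,vitamin_k,AI,120,mg,value conventionally in ug; stored in as-printed panel unit
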