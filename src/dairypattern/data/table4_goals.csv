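metric,nutrient_id,kind,goal_type,m1_f,m1_m,m2_f,m2_m,m3_f,m3_m,m4_f,m4_m,m5_f,m5_m,m6_f,m6_m,m7_f,m7_m
kcal_pct_goal,energy,energy_vs_goal,energy,100,100,103,103,104,104,104,104,102,102,105,105,103,103
protein_pct_rda,protein,amount_vs_goal,RDA,207,170,204,167,202,166,201,165,202,166,204,167,205,169
protein_pct_kcal,protein,pct_kcal,kcal,19,19,18,18,18,18,18,18,18,18,18,18,18,18
carbohydrate_pct_rda,carbohydrate,amount_vs_goal,RDA,199,199,199,199,198,198,201,201,201,201,196,196,196,196
carbohydrate_pct_kcal,carbohydrate,pct_kcal,kcal,52,52,50,50,49,49,50,50,51,51,48,48,50,50
fiber_pct_ai,fiber,amount_vs_goal,AI,109,109,109,109,109,109,109,109,109,109,109,109,109,109
saturated_fat_pct_kcal,saturated_fat,pct_kcal,kcal,8,8,9,9,10,10,9,9,9,9,10,10,10,10
monounsaturated_fat_pct_kcal,monounsaturated_fat,pct_kcal,kcal,11,11,12,12,12,12,12,12,12,12,12,12,12,12
polyunsaturated_fat_pct_kcal,polyunsaturated_fat,pct_kcal,kcal,10,10,10,10,10,10,10,10,10,10,10,10,10,10
linoleic_acid_pct_ai,linoleic_acid,amount_vs_goal,AI,162,139,164,140,165,142,165,141,164,140,166,142,164,140
linolenic_acid_pct_ai,linolenic_acid,amount_vs_goal,AI,207,142,211,145,217,149,223,153,208,143,211,145,214,147
calcium_pct_rda,calcium,amount_vs_goal,RDA,149,124,142,118,162,135,139,116,141,118,188,157,141,118
iron_pct_rda,iron,amount_vs_goal,RDA,94,210,94,211,95,213,94,211,94,210,96,216,94,211
magnesium_pct_rda,magnesium,amount_vs_goal,RDA,137,101,130,96,130,96,131,96,132,97,129,95,129,95
phosphorus_pct_rda,phosphorus,amount_vs_goal,RDA,238,238,256,256,251,251,236,236,239,239,268,268,273,273
potassium_pct_ai,potassium,amount_vs_goal,AI,76,76,75,75,75,75,76,76,77,77,73,73,73,73
sodium_pct_ul,sodium,amount_vs_goal,UL,103,103,102,102,103,103,91,91,91,91,117,117,115,115
zinc_pct_rda,zinc,amount_vs_goal,RDA,196,142,191,139,189,137,186,135,190,138,190,138,191,139
copper_pct_rda,copper,amount_vs_goal,RDA,210,210,193,193,196,196,198,198,193,193,193,193,193,193
selenium_pct_rda,selenium,amount_vs_goal,RDA,206,206,204,204,208,208,208,208,203,203,208,208,205,205
vitamin_a_pct_rda,vitamin_a,amount_vs_goal,RDA,123,95,129,100,128,100,126,98,129,101,132,102,130,101
vitamin_e_pct_rda,vitamin_e,amount_vs_goal,RDA,69,69,69,69,70,70,69,69,69,69,71,71,69,69
vitamin_d_pct_rda,vitamin_d,amount_vs_goal,RDA,47,47,56,56,59,59,57,57,56,56,60,60,56,56
vitamin_c_pct_rda,vitamin_c,amount_vs_goal,RDA,156,130,156,130,156,130,156,130,157,130,156,130,156,130
thiamin_pct_rda,thiamin,amount_vs_goal,RDA,180,165,171,157,171,157,175,161,174,159,167,153,169,155
riboflavin_pct_rda,riboflavin,amount_vs_goal,RDA,214,181,213,180,209,177,217,184,221,187,201,170,204,173
niacin_pct_rda,niacin,amount_vs_goal,RDA,202,177,192,168,192,168,192,168,192,168,191,167,191,167
vitamin_b6_pct_rda,vitamin_b6,amount_vs_goal,RDA,208,159,199,152,199,152,200,153,200,153,198,152,197,150
vitamin_b12_pct_rda,vitamin_b12,amount_vs_goal,RDA,320,320,313,313,313,313,318,318,326,326,308,308,299,299
choline_pct_rda,choline,amount_vs_goal,AI,86,66,86,67,86,66,87,67,88,68,84,65,84,65
vitamin_k_pct_rda,vitamin_k,amount_vs_goal,AI,155,116,156,117,156,117,155,117,155,116,157,117,156,117
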