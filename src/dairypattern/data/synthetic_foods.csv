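food_code,description,group,fat_tier,energy__kcal,protein__g,carbohydrate__g,fiber__g,total_fat__g,saturated_fat__g,monounsaturated_fat__g,polyunsaturated_fat__g,linoleic_acid__g,linolenic_acid__g,epa__g,dha__g,stearic_acid__g,cholesterol__mg,calcium__mg,iron__mg,magnesium__mg,phosphorus__mg,potassium__mg,sodium__mg,zinc__mg,copper__mg,selenium__mg,vitamin_a__ug_RAE,vitamin_e__mg_AT,vitamin_d__IU,vitamin_c__mg,thiamin__mg,riboflavin__mg,niacin__mg,vitamin_b6__mg,vitamin_b12__mg,choline__mg,vitamin_k__mg
11111000,SYNTHETIC stand-in: whole milk per cup-equivalent (non-authoritative),milk,whole,149,7.7,11.7,0,7.9,4.6,2.0,0.5,0.3,0.18,0,0,0.9,24,276,0.1,24,205,322,105,0.9,0.02,9.0,112,0.1,124,0,0.11,0.41,0.22,0.09,1.1,35,0.3
11112110,SYNTHETIC stand-in: reduced-fat milk per cup-equivalent (non-authoritative),milk,reduced_fat,122,8.1,11.7,0,4.8,3.1,1.4,0.2,0.15,0.07,0,0,0.6,20,293,0.1,27,224,342,115,1.1,0.01,6.1,134,0.1,120,0.5,0.1,0.45,0.22,0.09,1.3,40,0.2
14410110,SYNTHETIC stand-in: whole-fat cheese per cup-equivalent (non-authoritative),cheese,whole,171,9.7,1.3,0,14.1,8.1,3.8,0.6,0.4,0.15,0,0,1.6,42,307,0.1,12,194,41,274,1.6,0.01,12.0,140,0.3,10,0,0.01,0.2,0.03,0.03,0.5,7,1.0
14410120,SYNTHETIC stand-in: reduced-fat cheese per cup-equivalent (non-authoritative),cheese,reduced_fat,122,11.6,2.0,0,7.3,4.6,2.1,0.3,0.2,0.08,0,0,0.9,30,349,0.2,14,232,54,310,1.9,0.01,14.0,95,0.1,5,0,0.01,0.18,0.04,0.03,0.7,7,0.8
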