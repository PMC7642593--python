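nutrient_id,model1,model2,model2_pct,model3,model3_pct,model4,model4_pct,model5,model5_pct,model6,model6_pct,model7,model7_pct
energy,2006,2055,2.4,2084,3.9,2074,3.4,2048,2.1,2097,4.5,2060,27
protein,95,94,-1.1,93,-1.9,92,-2.6,93,-2.2,94,-1.2,95,-0.3
carbohydrate,259,258,-0.1,258,-0.4,261,0.9,261,0.9,254,-1.7,255,-1.3
fiber,30,30,0,30,0,30,0,30,0,30,0,30,0
total_fat,70,76,8.6,80,14.3,77,11.0,74,6.7,82,18.1,77,11.0
saturated_fat,17.3,21.1,21.9,22.9,32.7,21.7,25.5,20.2,17.0,24.3,40.7,22.1,27.7
monounsaturated_fat,25.5,27.3,6.8,28.0,9.7,27.5,7.5,26.9,5.1,28.6,12.1,27.8,8.8
polyunsaturated_fat,22.3,22.5,0.9,22.8,2.2,22.8,2.2,22.5,0.8,22.8,2.4,22.5,1.0
linoleic_acid,19.5,19.6,0.7,19.8,1.8,19.8,1.5,19.6,0.8,19.9,2.2,19.6,0.8
linolenic_acid,2.3,2.3,2.1,2.4,4.9,2.5,7.9,2.3,0.8,2.3,2.2,2.4,3.6
epa,0.07,0.07,0,0.07,3.0,0.07,0,0.07,0,0.07,6.3,0.07,0
dha,0.15,0.15,0,0.15,0.4,0.15,0,0.15,0,0.15,0.7,0.15,0
stearic_acid,4.39,5.09,16.0,5.41,23.3,5.25,19.7,4.96,13.0,5.60,27.7,5.26,19.9
cholesterol,222,236,6.5,246,10.8,237,6.6,232,4.5,255,15.2,242,9.0
calcium,1491,1419,-4.8,1624,9.0,1395,-6.4,1411,-5.3,1880,26.1,1414,-5.1
iron,17,17,0.2,17,1.4,17,0.2,17,0,17,2.8,17,0.4
magnesium,426,404,-5.1,403,-5.4,405,-4.8,408,-4.3,400,-6.1,399,-6.2
phosphorus,1667,1789,7.3,1758,5.5,1653,-0.8,1673,0.3,1874,12.4,1908,14.4
potassium,3571,3534,-1.0,3507,-1.8,3578,0.2,3598,0.8,3424,-4.1,3443,-3.6
sodium,2378,2353,-1.1,2366,-0.5,2082,-12.4,2092,-12.0,2683,12.8,2640,11.0
zinc,16,15,-2.5,15,-3.8,15,-4.9,15,-3.2,15,-2.8,15,-2.3
copper,1.9,1.7,-7.7,1.8,-6.6,1.8,-5.4,1.7,-7.8,1.7,-7.8,1.7,-7.7
selenium,113,112,-1.1,114,0.8,115,1.0,112,1.5,115,1.0,113,-0.8
vitamin_a,858,903,5.2,899,4.8,885,30,905,5.5,922,7.4,911,6.2
vitamin_e,10.3,10.4,0.3,10.5,2.2,10.4,0.8,10.3,-0.1,10.7,3.7,10.4,0.7
vitamin_d,280,334,19.3,351,25.4,344,22.6,334,19.2,362,29.1,335,19.7
vitamin_c,117,117,0.2,117,0,117,-0.1,117,0.3,117,-0.1,117,-0.1
thiamin,2.0,1.9,-4.9,1.9,-4.9,1.9,-2.7,1.9,-3.6,1.8,-7.2,1.9,-6.3
riboflavin,2.4,2.3,-0.7,2.3,-2.3,2.4,1.2,2.4,2.9,2.2,-6.0,2.2,-4.8
niacin,28,27,-5.0,27,-5.0,27,-4.8,27,-4.8,27,-5.2,27,-5.2
vitamin_b6,2.7,2.6,-4.7,2.6,-4.4,2.6,-4.0,2.6,-3.9,2.6,-4.7,2.6,-5.6
vitamin_b12,7.7,7.5,-2.1,7.5,-2.2,7.6,-0.6,7.8,2.0,7.4,-3.7,7.2,-6.7
choline,366,366,0.1,364,-0.6,370,1.3,375,2.7,356,-2.7,356,-2.6
vitamin_k,139,140,0.6,140,0.8,140,0.5,140,0.3,141,1.2,141,1.0
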