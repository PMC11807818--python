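parameter,global_mean,global_sd,weight
energy_kcal,2056.0,338.0,0.180
carbohydrate_g,272.2,40.0,0.097
protein_g,79.4,13.9,0.021
total_fat_g,71.4,19.4,0.298
saturated_fat_g,28.6,8.0,0.373
mufa_g,27.0,6.1,-0.009
pufa_g,13.88,3.76,-0.337
omega3_g,1.06,1.06,-0.436
omega6_g,10.8,7.5,-0.159
trans_fat_g,3.15,3.75,0.229
cholesterol_mg,279.4,51.2,0.110
fibre_g,18.8,4.9,-0.663
vitamin_a_ug,983.9,518.6,-0.401
vitamin_b6_mg,1.47,0.74,-0.365
vitamin_b12_ug,5.15,2.70,0.106
vitamin_c_mg,118.2,43.46,-0.424
vitamin_d_ug,6.26,2.21,-0.446
vitamin_e_mg,8.73,1.49,-0.419
folate_ug,273.0,70.7,-0.190
iron_mg,13.35,3.71,0.032
magnesium_mg,310.1,139.4,-0.484
niacin_mg,25.90,11.77,-0.246
riboflavin_mg,1.70,0.79,-0.068
thiamin_mg,1.70,0.66,-0.098
zinc_mg,9.84,2.19,-0.313
selenium_ug,67.0,25.1,-0.191
caffeine_g,8.05,6.67,-0.110
alcohol_g,13.98,3.72,-0.278
tea_g,1.69,1.53,-0.536
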