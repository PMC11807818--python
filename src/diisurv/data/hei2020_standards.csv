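component,max_points,direction,unit,score0_standard,scoremax_standard,kcal_per_g
total_fruits,5,adequacy,density,0.0,0.8,
whole_fruits,5,adequacy,density,0.0,0.4,
total_vegetables,5,adequacy,density,0.0,1.1,
greens_and_beans,5,adequacy,density,0.0,0.2,
whole_grains,10,adequacy,density,0.0,1.5,
dairy,10,adequacy,density,0.0,1.3,
total_protein_foods,5,adequacy,density,0.0,2.5,
seafood_plant_proteins,5,adequacy,density,0.0,0.8,
fatty_acids,10,adequacy,ratio,1.2,2.5,
refined_grains,10,moderation,density,4.3,1.8,
sodium,10,moderation,density,2.0,1.1,
added_sugars,10,moderation,pct_energy,26.0,6.5,4.0
saturated_fats,10,moderation,pct_energy,16.0,8.0,9.0
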