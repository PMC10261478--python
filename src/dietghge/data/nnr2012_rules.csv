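rule_id,nutrient,kind,sex,age_min,age_max,low,high,direction
protein_range,protein,range_epct,both,18,80,10,20,
fat_range,fat,range_epct,both,18,80,25,40,
mufa_range,mufa,range_epct,both,18,80,10,20,
pufa_range,pufa,range_epct,both,18,80,5,10,
carbohydrate_range,carbohydrate,range_epct,both,18,80,45,60,
sfa_upper,sfa,upper_epct,both,18,80,,10,
added_sugar_upper,added_sugar,upper_epct,both,18,80,,10,
linoleic_lower,linoleic_g,lower_threshold,both,18,80,3.0,,
ala_lower,ala_g,lower_threshold,both,18,80,1.2,,
fibre_lower,fibre_g,lower_threshold,both,18,80,25.0,,
vitamin_a_ar_f,vitamin_a_ug,ar,F,18,80,400,,
vitamin_a_ar_m,vitamin_a_ug,ar,M,18,80,500,,
vitamin_d_ar,vitamin_d_ug,ar,both,18,80,7.5,,
vitamin_e_ar_f,vitamin_e_mg,ar,F,18,80,5,,
vitamin_e_ar_m,vitamin_e_mg,ar,M,18,80,6,,
thiamin_ar_f,thiamin_mg,ar,F,18,80,0.9,,
thiamin_ar_m,thiamin_mg,ar,M,18,80,1.2,,
riboflavin_ar_f,riboflavin_mg,ar,F,18,80,1.1,,
riboflavin_ar_m,riboflavin_mg,ar,M,18,80,1.4,,
niacin_ar_f,niacin_mg,ar,F,18,80,12,,
niacin_ar_m,niacin_mg,ar,M,18,80,15,,
vitamin_b6_ar_f,vitamin_b6_mg,ar,F,18,80,1.0,,
vitamin_b6_ar_m,vitamin_b6_mg,ar,M,18,80,1.3,,
folate_ar,folate_ug,ar,both,18,80,200,,
vitamin_b12_ar,vitamin_b12_ug,ar,both,18,80,1.4,,
vitamin_c_ar_f,vitamin_c_mg,ar,F,18,80,50,,
vitamin_c_ar_m,vitamin_c_mg,ar,M,18,80,60,,
calcium_ar,calcium_mg,ar,both,18,80,500,,
iron_ar_f_young,iron_mg,ar,F,18,50,10,,
iron_ar_f_older,iron_mg,ar,F,51,80,6,,
iron_ar_m,iron_mg,ar,M,18,80,7,,
zinc_ar_f,zinc_mg,ar,F,18,80,5,,
zinc_ar_m,zinc_mg,ar,M,18,80,6,,
selenium_ar_f,selenium_ug,ar,F,18,80,30,,
selenium_ar_m,selenium_ug,ar,M,18,80,35,,
potassium_li,potassium_mg,li,both,18,80,1600,,
magnesium_ri_f,magnesium_mg,ri,F,18,80,280,,
magnesium_ri_m,magnesium_mg,ri,M,18,80,350,,
sodium_ri,sodium_mg,ri,both,18,80,2400,,le
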