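sex,height_m,weight_kg,bmi_kg_m2,waist_circumference_cm,visceral_fat_area_cm2,true_volume_cm3,calculated_volume_cm3
female,1.64,41,15.2,70.0,50,833,926
female,1.57,42,17.0,65.5,21,216,243
female,1.53,43,18.4,75.5,22,73,195
female,1.47,44,20.4,68.5,36,1003,1054
female,1.44,47,22.7,83.0,66,1598,1697
female,1.56,59,24.2,80.5,116,3463,3565
female,1.53,65,27.8,98.0,120,4955,5076
female,1.40,56,28.6,98.0,111,3198,3340
female,1.55,71,29.6,104.5,153,1955,2026
female,1.57,77,31.2,112.5,217,5936,6149
female,1.47,69,31.9,101.0,99,3805,3910
female,1.55,84,35.0,115.0,203,5159,5426
male,1.68,50,17.7,71.0,30,603,624
male,1.62,47,17.9,72.0,44,891,908
male,1.79,59,18.4,77.0,66,1306,1348
male,1.68,62,22.0,78.0,99,3074,3239
male,1.56,58,23.8,87.0,99,3081,3266
male,1.65,66,24.2,85.0,124,3583,3726
male,1.75,84,27.4,97.5,141,4647,4820
male,1.71,81,27.7,89.0,117,4029,4137
male,1.61,74,28.5,88.0,125,5393,5595
male,1.58,78,31.2,111.0,192,4587,4748
male,1.77,100,31.9,106.0,188,7837,8170
male,1.80,109,33.6,115.0,220,5819,6069
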