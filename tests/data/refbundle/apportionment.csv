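food_code,source_group,servings_per_100g
10000001,whole_grains,0.55
10000002,fruits,0.67
10000003,vegetables,1.33
10000004,legumes,0.57
10000005,refined_grains,1.4
10000006,sugars_syrups,0.88
10000007,plant_oils,2.5
10000008,dairy_high_fat,0.9
10000008,misc_animal,0.1
10000009,eggs,0.83
10000010,red_meat_fatty,1.0
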