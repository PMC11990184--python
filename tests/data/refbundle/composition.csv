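food_code,description,energy_density_kj_100g,is_recipe
10000001,"Brown rice, cooked",470,False
10000002,"Apple, raw",220,False
10000003,"Carrot, raw",120,False
10000004,"Lentils, boiled",380,False
10000005,"White bread",1000,False
10000006,"Cola soft drink",180,False
10000007,"Olive oil",3700,False
10000008,"Cheddar cheese",1700,False
10000009,"Egg, boiled",550,False
10000010,"Beef mince, cooked",1050,False
11000001,"Vegetable stew, homemade",0,True
11000002,"Fried rice, homemade",0,True
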