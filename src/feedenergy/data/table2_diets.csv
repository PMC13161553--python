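diet_id,ingredient_id,inclusion,energy_free,is_test
1,corn,96.96,0,1
1,dicalcium_phosphate,1.23,1,0
1,limestone,1.21,1,0
1,salt,0.46,1,0
1,premix,0.14,1,0
2,wheat,97.58,0,1
2,dicalcium_phosphate,0.88,1,0
2,limestone,0.95,1,0
2,salt,0.45,1,0
2,premix,0.14,1,0
3,sorghum,97.37,0,1
3,dicalcium_phosphate,1.01,1,0
3,limestone,1.02,1,0
3,salt,0.46,1,0
3,premix,0.14,1,0
4,barley,97.24,0,1
4,dicalcium_phosphate,1.14,1,0
4,limestone,1.03,1,0
4,salt,0.45,1,0
4,premix,0.14,1,0
5,wheat_flour,97.19,0,1
5,dicalcium_phosphate,1.09,1,0
5,limestone,1.12,1,0
5,salt,0.46,1,0
5,premix,0.14,1,0
6,brown_rice,96.86,0,1
6,dicalcium_phosphate,1.37,1,0
6,limestone,1.17,1,0
6,salt,0.46,1,0
6,premix,0.14,1,0
7,corn,37.07,0,0
7,wheat_middling,60.06,0,1
7,dicalcium_phosphate,1.07,1,0
7,limestone,1.2,1,0
7,salt,0.46,1,0
7,premix,0.14,1,0
8,corn,66.71,0,0
8,rice_bran,30.36,0,1
8,dicalcium_phosphate,1.06,1,0
8,limestone,1.27,1,0
8,salt,0.46,1,0
8,premix,0.14,1,0
9,corn,66.71,0,0
9,defatted_rice_bran,30.48,0,1
9,dicalcium_phosphate,0.96,1,0
9,limestone,1.25,1,0
9,salt,0.46,1,0
9,premix,0.14,1,0
10,corn,67.86,0,0
10,soybean_meal_1,29.44,0,1
10,dicalcium_phosphate,1.06,1,0
10,limestone,1.04,1,0
10,salt,0.46,1,0
10,premix,0.14,1,0
11,corn,68.06,0,0
11,soybean_meal_2,29.24,0,1
11,dicalcium_phosphate,1.06,1,0
11,limestone,1.04,1,0
11,salt,0.46,1,0
11,premix,0.14,1,0
12,corn,67.17,0,0
12,fermented_soybean_meal,30.28,0,1
12,dicalcium_phosphate,1.04,1,0
12,limestone,0.92,1,0
12,salt,0.45,1,0
12,premix,0.14,1,0
13,corn,70.41,0,0
13,enzyme_hydrolyzed_soybean_meal,26.89,0,1
13,dicalcium_phosphate,1.05,1,0
13,limestone,1.06,1,0
13,salt,0.45,1,0
13,premix,0.14,1,0
14,corn,71.38,0,0
14,extruded_soybean,25.87,0,1
14,dicalcium_phosphate,1.18,1,0
14,limestone,0.98,1,0
14,salt,0.45,1,0
14,premix,0.14,1,0
15,corn,76.45,0,0
15,soy_protein_concentrate,20.8,0,1
15,dicalcium_phosphate,1.05,1,0
15,limestone,1.11,1,0
15,salt,0.45,1,0
15,premix,0.14,1,0
16,corn,76.88,0,0
16,cottonseed_meal,20.33,0,1
16,dicalcium_phosphate,0.9,1,0
16,limestone,1.29,1,0
16,salt,0.46,1,0
16,premix,0.14,1,0
17,corn,72.6,0,0
17,rapeseed_meal,25.0,0,1
17,dicalcium_phosphate,0.85,1,0
17,limestone,0.95,1,0
17,salt,0.46,1,0
17,premix,0.14,1,0
18,corn,71.9,0,0
18,sunflower_meal,25.46,0,1
18,dicalcium_phosphate,0.98,1,0
18,limestone,1.06,1,0
18,salt,0.46,1,0
18,premix,0.15,1,0
19,corn,71.22,0,0
19,rice_ddgs,25.97,0,1
19,dicalcium_phosphate,1.12,1,0
19,limestone,1.1,1,0
19,salt,0.45,1,0
19,premix,0.14,1,0
20,corn,71.94,0,0
20,wheat_bran,25.19,0,1
20,dicalcium_phosphate,0.91,1,0
20,limestone,1.36,1,0
20,salt,0.46,1,0
20,premix,0.14,1,0
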