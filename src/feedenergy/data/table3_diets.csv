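diet_id,ingredient_id,inclusion,energy_free,is_test
v1,corn,62.44,0,0
v1,soybean_meal_1,26.81,0,0
v1,wheat_bran,8.08,0,0
v1,dicalcium_phosphate,0.97,1,0
v1,limestone,1.1,1,0
v1,salt,0.46,1,0
v1,premix,0.14,1,0
v2,corn,32.2,0,0
v2,wheat,20.36,0,0
v2,brown_rice,19.75,0,0
v2,soybean_meal_1,25.05,0,0
v2,dicalcium_phosphate,1.03,1,0
v2,limestone,1.01,1,0
v2,salt,0.46,1,0
v2,premix,0.14,1,0
v3,corn,31.13,0,0
v3,sorghum,19.92,0,0
v3,barley,20.24,0,0
v3,soybean_meal_1,26.12,0,0
v3,dicalcium_phosphate,1.01,1,0
v3,limestone,0.98,1,0
v3,salt,0.46,1,0
v3,premix,0.14,1,0
v4,corn,32.11,0,0
v4,wheat,10.18,0,0
v4,sorghum,9.96,0,0
v4,brown_rice,9.87,0,0
v4,soybean_meal_1,25.13,0,0
v4,rice_bran,10.14,0,0
v4,dicalcium_phosphate,0.97,1,0
v4,limestone,1.04,1,0
v4,salt,0.46,1,0
v4,premix,0.14,1,0
v5,corn,34.82,0,0
v5,barley,10.11,0,0
v5,wheat_flour,9.94,0,0
v5,wheat_middling,10.01,0,0
v5,soybean_meal_1,22.32,0,0
v5,defatted_rice_bran,10.18,0,0
v5,dicalcium_phosphate,0.95,1,0
v5,limestone,1.07,1,0
v5,salt,0.46,1,0
v5,premix,0.14,1,0
v6,corn,46.15,0,0
v6,wheat,10.02,0,0
v6,wheat_flour,9.8,0,0
v6,fermented_soybean_meal,21.55,0,0
v6,rice_bran,9.99,0,0
v6,dicalcium_phosphate,0.95,1,0
v6,limestone,0.95,1,0
v6,salt,0.45,1,0
v6,premix,0.14,1,0
v7,corn,57.78,0,0
v7,cottonseed_meal,15.13,0,0
v7,sunflower_meal,14.42,0,0
v7,defatted_rice_bran,10.14,0,0
v7,dicalcium_phosphate,0.75,1,0
v7,limestone,1.19,1,0
v7,salt,0.45,1,0
v7,premix,0.14,1,0
v8,corn,61.44,0,0
v8,soy_protein_concentrate,5.21,0,0
v8,rapeseed_meal,19.83,0,0
v8,rice_ddgs,11.17,0,0
v8,dicalcium_phosphate,0.83,1,0
v8,limestone,0.93,1,0
v8,salt,0.45,1,0
v8,premix,0.14,1,0
v9,corn,61.24,0,0
v9,soybean_meal_1,8.05,0,0
v9,cottonseed_meal,10.18,0,0
v9,rapeseed_meal,9.97,0,0
v9,wheat_bran,8.06,0,0
v9,dicalcium_phosphate,0.76,1,0
v9,limestone,1.14,1,0
v9,salt,0.46,1,0
v9,premix,0.14,1,0
v10,corn,62.85,0,0
v10,soybean_meal_1,10.88,0,0
v10,extruded_soybean,10.38,0,0
v10,soy_protein_concentrate,5.21,0,0
v10,wheat_bran,8.02,0,0
v10,dicalcium_phosphate,0.99,1,0
v10,limestone,1.08,1,0
v10,salt,0.45,1,0
v10,premix,0.14,1,0
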