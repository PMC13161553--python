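ingredient_id,dm,ge,cp,ee,ash,ndf,adf
corn,88.12,4459,9.6,4.11,1.68,10.23,1.98
wheat,90.4,4422,14.62,2.05,1.64,12.39,2.96
sorghum,88.2,4470,10.48,2.36,1.65,9.46,2.62
barley,89.91,4354,10.86,2.89,2.66,19.01,6.07
wheat_flour,87.08,4418,14.15,1.97,1.33,7.58,0.69
brown_rice,86.81,4377,9.79,2.33,1.57,4.55,1.24
wheat_middling,88.64,4553,20.48,2.97,3.38,21.09,5.49
soybean_meal_1,88.15,4684,50.84,1.82,6.68,12.6,7.04
soybean_meal_2,87.14,4655,54.63,1.02,7.15,10.93,5.7
fermented_soybean_meal,93.05,4744,57.36,1.66,7.22,22.47,8.41
enzyme_hydrolyzed_soybean_meal,89.46,4812,61.49,1.42,8.1,17.65,3.72
extruded_soybean,91.96,5750,40.13,23.23,5.17,13.98,6.19
soy_protein_concentrate,91.43,4885,72.06,1.29,6.92,24.19,4.63
cottonseed_meal,89.89,4647,51.35,0.65,6.97,31.32,16.17
rapeseed_meal,88.22,4724,42.97,1.96,7.27,28.37,19.82
sunflower_meal,90.13,4650,42.0,2.33,6.91,30.96,19.87
rice_ddgs,92.87,4950,25.32,8.57,9.82,65.13,38.75
rice_bran,90.45,5040,14.0,20.08,7.59,14.09,5.09
defatted_rice_bran,89.76,4150,17.5,1.18,9.42,20.55,9.81
wheat_bran,90.06,4584,18.62,2.55,5.48,41.58,12.97
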