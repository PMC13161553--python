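ingredient_id,ivde,cv_ivde,de,cv_de,me,cv_me,ratio_ivde_de,ratio_ivde_me,pred_de,pred_de_lo,pred_de_hi,pred_me,pred_me_lo,pred_me_hi
corn,3969,0.12,3986,1.13,3892,1.35,1.0,1.02,4155,3984,4326,4001,3860,4141
wheat,3867,0.3,3854,1.56,3777,2.22,1.0,1.02,4053,3892,4214,3897,3765,4029
sorghum,4012,0.28,3886,1.1,3802,1.38,1.03,1.06,4198,4022,4374,4044,3899,4189
barley,3337,0.56,3363,2.23,3295,2.34,0.99,1.01,3522,3370,3673,3359,3234,3483
wheat_flour,4197,0.19,4159,1.1,4050,0.86,1.01,1.04,4383,4182,4584,4232,4067,4397
brown_rice,4156,0.19,4034,0.68,3987,0.66,1.03,1.04,4342,4147,4537,4190,4030,4351
wheat_middling,3452,0.39,3748,2.88,3655,1.85,0.92,0.94,3637,3491,3784,3476,3355,3596
soybean_meal_1,3709,0.44,4377,2.67,4110,3.4,0.85,0.9,3894,3745,4044,3737,3613,3860
soybean_meal_2,3734,0.47,4245,3.02,4064,4.07,0.88,0.92,3920,3768,4071,3762,3638,3886
fermented_soybean_meal,3627,0.31,4260,2.06,4019,2.24,0.85,0.9,3812,3666,3959,3653,3533,3774
enzyme_hydrolyzed_soybean_meal,3872,0.32,4271,4.21,3983,6.86,0.91,0.97,4058,3896,4219,3902,3769,4035
extruded_soybean,4975,0.14,5135,4.09,4906,1.94,0.97,1.01,5162,4827,5497,5022,4747,5297
soy_protein_concentrate,3822,0.2,4556,1.03,4336,3.96,0.84,0.88,4008,3850,4165,3851,3722,3980
cottonseed_meal,2861,0.72,2996,2.24,2725,8.27,0.95,1.05,3045,2842,3249,2876,2708,3043
rapeseed_meal,2946,0.35,3440,5.41,3110,7.55,0.86,0.95,3130,2939,3322,2962,2805,3119
sunflower_meal,2954,0.77,2846,6.54,2650,9.5,1.04,1.11,3138,2948,3329,2970,2814,3126
rice_ddgs,1910,1.37,1774,4.46,1638,3.6,1.08,1.17,2093,1722,2464,1910,1605,2215
rice_bran,4076,0.54,3891,4.2,3842,2.88,1.05,1.06,4262,4078,4446,4109,3958,4261
defatted_rice_bran,2966,0.41,2960,4.4,2877,4.96,1.0,1.03,3150,2962,3339,2982,2827,3137
wheat_bran,2320,0.64,2686,4.67,2543,4.25,0.86,0.91,2504,2209,2798,2326,2085,2568
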