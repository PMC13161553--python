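pig_id,batch,period,diet_id,dmi,gei,geo,geu,pseudo
mean_d1,1,1,1,1.356,5867,626,123,1
mean_d2,1,1,2,1.384,5986,761,102,1
mean_d3,1,1,3,1.214,5291,688,96,1
mean_d4,1,1,4,1.292,5470,1247,85,1
mean_d5,1,1,5,1.181,5089,301,125,1
mean_d6,1,1,6,1.237,5263,415,55,1
mean_d7,1,1,7,1.309,5761,859,118,1
mean_d8,1,1,8,1.264,5677,838,99,1
mean_d9,1,1,9,1.29,5470,875,112,1
mean_d10,1,1,10,1.448,6390,601,206,1
mean_d11,1,1,11,1.353,5948,597,160,1
mean_d12,1,1,12,1.366,6055,632,186,1
mean_d13,1,1,13,1.332,5908,631,192,1
mean_d14,1,1,14,1.441,6710,713,180,1
mean_d15,1,1,15,1.351,5983,581,158,1
mean_d16,1,1,16,1.422,6225,995,179,1
mean_d17,1,1,17,1.434,6333,949,217,1
mean_d18,1,1,18,1.239,5450,988,140,1
mean_d19,1,1,19,1.335,5964,1550,137,1
mean_d20,1,1,20,1.344,5845,1096,141,1
mean_dv1,1,1,v1,1.41,6245,777,158,1
mean_dv2,1,1,v2,1.358,5962,587,152,1
mean_dv3,1,1,v3,1.289,5679,764,120,1
mean_dv4,1,1,v4,1.383,6168,772,95,1
mean_dv5,1,1,v5,1.299,5682,783,80,1
mean_dv6,1,1,v6,1.288,5742,705,138,1
mean_dv7,1,1,v7,1.299,5683,1201,153,1
mean_dv8,1,1,v8,1.424,6397,1328,201,1
mean_dv9,1,1,v9,1.415,6274,1124,166,1
mean_dv10,1,1,v10,1.415,6452,827,189,1
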