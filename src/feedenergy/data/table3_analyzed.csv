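diet_id,dm,ge,cp,ash,ndf,adf
v1,88.09,4428,20.78,5.4,11.84,3.97
v2,88.08,4391,20.42,5.07,8.66,3.1
v3,88.14,4407,20.26,5.18,11.8,4.46
v4,88.14,4460,20.68,5.47,9.68,3.61
v5,88.41,4373,20.95,5.84,12.37,4.59
v6,89.47,4459,21.08,5.45,10.18,3.42
v7,88.69,4376,20.76,5.99,13.99,6.78
v8,88.72,4491,20.81,5.72,18.5,9.37
v9,88.33,4434,20.73,5.4,14.73,6.19
v10,88.9,4561,20.69,5.15,12.12,3.98
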