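diet_id,quantity,determined,predicted,difference,sem,p_value
v1,DE,3872,3841,31,25.3,0.275
v2,DE,3959,3996,-37,18.6,0.102
v3,DE,3814,3860,-46,19.5,0.076
v4,DE,3900,4004,-104,15.6,0.001
v5,DE,3770,3792,-22,13.9,0.181
v6,DE,3914,4000,-86,17.5,0.004
v7,DE,3450,3633,-183,6.3,<0.001
v8,DE,3554,3616,-62,24.4,0.053
v9,DE,3640,3682,-42,19.1,0.093
v10,DE,3976,3980,-4,10.1,0.702
v1,ME,3759,3688,71,33.2,0.086
v2,ME,3841,3846,-5,40.7,0.919
v3,ME,3720,3707,13,9.2,0.236
v4,ME,3830,3854,-24,18.7,0.256
v5,ME,3700,3639,61,25.3,0.061
v6,ME,3801,3850,-49,22.1,0.077
v7,ME,3331,3478,-147,13.0,<0.001
v8,ME,3417,3460,-43,19.3,0.077
v9,ME,3523,3527,-4,22.4,0.880
v10,ME,3842,3830,12,11.3,0.376
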