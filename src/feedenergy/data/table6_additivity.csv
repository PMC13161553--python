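diet_id,quantity,determined,calculated,difference
v1,GE,4428,4410,18
v2,GE,4391,4374,17
v3,GE,4407,4383,24
v4,GE,4460,4447,13
v5,GE,4373,4356,17
v6,GE,4459,4460,-1
v7,GE,4376,4371,5
v8,GE,4491,4484,7
v9,GE,4434,4421,13
v10,GE,4561,4531,30
v1,IVDE,3643,3660,-17
v2,IVDE,3817,3815,2
v3,IVDE,3670,3679,-9
v4,IVDE,3823,3823,0
v5,IVDE,3606,3612,-6
v6,IVDE,3823,3819,4
v7,IVDE,3453,3453,0
v8,IVDE,3422,3435,-13
v9,IVDE,3504,3501,3
v10,IVDE,3801,3800,1
v1,DE,3872,3879,-7
v2,DE,3959,3961,-2
v3,DE,3814,3839,-25
v4,DE,3900,3952,-52
v5,DE,3770,3795,-25
v6,DE,3914,3940,-26
v7,DE,3450,3467,-17
v8,DE,3554,3567,-13
v9,DE,3640,3658,-18
v10,DE,3976,3967,9
v1,ME,3759,3738,21
v2,ME,3841,3839,2
v3,ME,3720,3709,11
v4,ME,3830,3829,1
v5,ME,3700,3667,33
v6,ME,3801,3821,-20
v7,ME,3331,3335,-4
v8,ME,3417,3417,0
v9,ME,3523,3507,16
v10,ME,3842,3833,9
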