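diet_id,dm,ge,cp,ash,ndf,adf
1,88.0,4327,9.2,4.13,8.58,1.95
2,89.71,4325,14.79,3.61,9.81,2.72
3,88.09,4358,9.99,3.63,9.25,2.62
4,89.74,4234,10.43,4.88,18.32,6.49
5,87.96,4308,13.58,3.76,6.94,0.34
6,87.79,4253,9.62,4.02,3.15,0.95
7,88.65,4401,15.44,4.91,15.65,3.97
8,89.53,4490,10.31,5.86,10.92,3.1
9,89.31,4239,11.19,6.35,12.2,4.42
10,88.29,4414,21.64,5.23,10.05,3.54
11,87.89,4396,22.06,5.3,9.25,3.03
12,89.81,4432,23.71,5.28,13.33,3.78
13,89.46,4435,22.86,5.57,10.72,2.41
14,89.69,4657,16.87,4.91,8.97,3.24
15,88.62,4430,21.44,5.04,11.8,4.24
16,88.75,4377,17.35,5.16,11.29,4.62
17,88.32,4417,17.29,4.89,13.63,6.2
18,88.88,4397,16.31,5.23,13.13,6.22
19,89.65,4467,12.78,6.01,23.53,11.96
20,89.11,4349,11.38,4.89,16.6,4.78
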