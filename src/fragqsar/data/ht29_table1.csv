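compound_id,role,r1_label,r2_label,exp_pic50,pred_pic50,residual,censored
1,test,COOH,OH,4.856,4.627,0.229,false
2,test,figure-only,OCOCH3,4.999,4.855,0.144,false
3,test,figure-only,OCOCH3,5.276,5.244,0.032,false
4,test,figure-only,OH,5.310,5.150,0.160,false
5,test,figure-only,OCOCH3,4.936,5.053,-0.118,false
6,test,figure-only,OCOCH3,4.921,4.953,-0.032,false
7,test,figure-only,OH,5.229,4.990,0.239,false
8,test,figure-only,OCOCH3,4.733,4.722,0.011,false
9,test,COOH,OCONHC2H5,4.776,4.806,-0.030,false
10,test,COOH,OCOC5H11,4.000,4.486,-0.486,true
11,test,CH2OCOCH3,OCOCH3,4.590,4.782,-0.192,false
12,train,COOH,OCOCH3,4.792,4.818,-0.026,false
13,train,figure-only,OCOCH3,5.611,5.384,0.227,false
14,train,figure-only,OH,5.051,5.192,-0.141,false
15,train,CH2OCOCH3,figure-only,5.009,4.970,0.039,false
16,train,CH2OCOCH3,figure-only,4.997,4.970,0.026,false
17,train,figure-only,OH,5.056,5.052,0.004,false
18,train,figure-only,OCOCH3,5.301,5.341,-0.040,false
19,train,figure-only,OCH3,5.328,5.334,-0.006,false
20,train,figure-only,OCOCH3,4.770,4.728,0.042,false
21,train,figure-only,OCOCH3,4.740,4.775,-0.035,false
22,train,figure-only,OCOCH3,5.244,5.296,-0.052,false
23,train,figure-only,OCOCH3,5.292,5.316,-0.024,false
24,train,figure-only,OCOCH3,5.409,5.421,-0.012,false
25,train,figure-only,OCOCH3,4.799,4.825,-0.026,false
26,train,figure-only,OH,4.813,4.711,0.102,false
27,train,figure-only,OH,4.740,4.711,0.029,false
28,train,figure-only,OCH3,4.775,4.715,0.060,false
29,train,figure-only,OCOCH3,4.524,4.527,-0.003,false
30,train,COCH2COOC2H5,OCOCH3,4.921,4.914,0.007,false
31,train,figure-only,OCOCH3,4.830,4.776,0.054,false
32,train,OCOOCH3,OCONHC6H5,4.161,4.125,0.036,false
33,train,CH2OCONHC2H5,OCONHC2H5,5.208,5.180,0.028,false
34,train,CH2OCONHC2H5,OCONHC6H5,4.160,4.176,-0.016,false
35,train,CH2OCOCH3,OCONHC6H5,4.117,4.116,0.001,false
36,train,COOH,OCOC9H19,4.279,4.287,-0.008,false
37,train,CH2OCOCH2Cl,OH,4.559,4.586,-0.027,false
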