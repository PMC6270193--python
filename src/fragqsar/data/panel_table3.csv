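compound_id,cell_line,ic50_uM,ic50_sd
BA,MPC2,38.58,2.91
BA,DU145,23.27,2.20
BA,NCI-H520,19.60,2.44
BA,HeLa,25.93,1.87
BA,2774,39.54,2.19
1,MPC2,75.07,4.96
1,DU145,92.54,1.45
1,NCI-H520,84.83,2.15
1,HeLa,99.62,4.64
1,2774,67.93,2.00
2,MPC2,31.28,3.43
2,DU145,36.19,2.77
2,NCI-H520,31.24,0.46
2,HeLa,40.05,3.37
2,2774,27.02,2.92
3,MPC2,22.79,0.35
3,DU145,37.99,2.50
3,NCI-H520,18.55,0.38
3,HeLa,17.47,1.48
3,2774,25.85,1.34
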