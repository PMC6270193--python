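compound_id,ic50_uM,ic50_sd,exp_pic50,pred_pic50,source
1,83.09,7.53,4.080,4.925,assayed
2,35.33,1.04,4.452,5.071,assayed
3,30.05,1.54,4.522,5.127,assayed
BA,32.66,0.62,4.486,4.627,assayed
BA,13.93,0.46,4.856,,literature
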