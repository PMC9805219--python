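trial_id,n_control,e_control,n_treat,e_treat,mean_control,sd_control,mean_treat,sd_treat,prop_z1_control,prop_z1_treat
1,112,30,118,19,54,11,54,9,71,71
2,89,28,85,16,53,11,55,11,73,67
3,49,11,30,1,55,9,53,7,71,73
4,53,13,53,13,57,12,55,11,76,74
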