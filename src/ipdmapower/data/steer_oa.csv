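trial_id,n_control,e_control,n_treat,e_treat,mean_control,sd_control,mean_treat,sd_treat,prop_z1_control,prop_z1_treat
1,68,39,142,88,64.25,12.21,65.29,11.46,22.06,30.99
2,24,9,24,15,67.17,8.13,65.17,6.72,20.83,37.50
3,44,18,45,30,64.59,7.55,64.52,9.05,54.55,48.89
4,99,40,100,64,62.54,5.36,60.96,5.92,30.30,40.00
5,74,40,148,75,62.28,6.77,63.93,9.39,36.49,28.38
6,159,55,153,56,69.63,6.26,69.86,6.82,37.74,36.60
7,63,22,63,40,64.94,9.43,63.21,8.38,26.98,22.22
8,41,19,111,83,69.61,6.10,70.39,6.28,17.07,29.73
9,43,16,45,28,60.37,9.91,61.76,9.49,46.51,24.44
10,16,9,23,8,75.19,4.58,73.57,7.3,25.00,21.74
11,108,60,109,73,68.23,7.98,67.94,8.54,35.19,34.86
12,23,10,25,7,61.30,7.06,65.03,8.91,26.09,12.00
13,35,13,36,29,61.53,7.80,63.34,9.55,31.43,33.33
14,49,20,56,32,65.20,5.73,65.43,5.27,12.24,21.43
15,140,71,278,193,66.76,8.72,66.52,8.25,31.43,28.78
16,147,78,71,50,59.11,9.99,57.79,10.42,59.18,59.15
17,54,16,53,33,63.56,8.73,65.62,8.21,46.30,43.40
18,78,44,80,40,68.61,6.13,69.02,6.55,NA,NA
19,40,17,40,26,58.20,4.26,57.25,3.98,NA,NA
20,44,29,43,30,63.91,2.36,63.81,2.41,0,0
21,9,6,19,13,70.44,7.83,66.37,5.55,44.44,47.37
22,11,5,21,16,71.18,5.25,72.43,6.52,9.09,14.29
23,54,27,55,38,57.21,9.82,58.4,10.00,48.15,43.64
24,54,21,55,23,68.60,6.87,66.85,7.41,27.78,34.55
25,20,10,20,15,67.10,5.36,66.14,8.74,35.00,5.00
26,17,11,17,10,70.76,4.71,69.59,6.74,23.53,23.53
27,102,66,101,64,66.59,9.56,64.18,8.52,45.10,37.62
28,156,78,235,110,61.89,9.59,61.54,9.58,35.90,36.17
29,27,16,28,20,78.93,8.30,78.89,6.91,33.33,21.43
30,102,55,98,77,67.78,9.22,68.29,8.45,20.59,22.45
31,23,4,23,7,66.78,7.27,67.57,7.86,52.17,60.87
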