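condition,chl_a_mg_g,chl_a_sd,car_mg_g,car_sd,car_chl_ratio
0.5 M NaCl,7.36,0.46,2.75,0.64,0.37
1.0 M NaCl,9.45,0.21,3.21,0.06,0.34
2.0 M NaCl,8.71,0.42,2.11,0.15,0.24
3.0 M NaCl,8.51,1.61,1.82,0.07,0.21
4.0 M NaCl,5.88,0.95,1.54,0.19,0.26
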