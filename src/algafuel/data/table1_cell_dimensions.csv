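condition,length_um,length_sd,width_um,width_sd,flagella_um,flagella_sd,volume_um3,volume_sd
0.5 M NaCl,6.45,0.50,4.38,0.32,12.93,0.58,65.39,12.55
1.0 M NaCl,6.97,0.49,5.03,0.49,11.98,0.28,93.08,18.53
2.0 M NaCl,7.04,0.51,4.59,0.33,12.40,0.77,78.11,12.18
3.0 M NaCl,8.01,0.91,4.52,0.26,12.07,0.84,86.56,16.52
4.0 M NaCl,8.75,0.71,4.96,0.46,13.21,0.76,114.12,26.36
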