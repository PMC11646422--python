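condition,protein_percent,protein_sd,lipid_percent,lipid_sd,carbohydrate_percent,carbohydrate_sd
0.5 M NaCl,21.45,2.73,15.71,0.89,53.14,2.89
1.0 M NaCl,30.35,0.18,17.81,2.40,42.02,5.20
2.0 M NaCl,26.26,1.42,16.96,0.54,27.87,1.25
3.0 M NaCl,24.50,1.78,16.17,1.13,25.68,2.04
4.0 M NaCl,18.48,2.16,12.67,0.48,18.67,2.51
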