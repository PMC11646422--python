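condition,sfa_percent,mufa_percent,pufa_percent
0.5 M NaCl,18.5,5.9,34.5
1.0 M NaCl,18.0,5.1,47.4
2.0 M NaCl,21.1,6.2,37.1
3.0 M NaCl,23.0,6.5,39.0
4.0 M NaCl,25.1,6.7,37.4
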