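condition,notation,mass_percent
0.5 M NaCl,C14:0,0.5
0.5 M NaCl,C16:0,17.0
0.5 M NaCl,C16:1,3.3
0.5 M NaCl,C18:0,1.0
0.5 M NaCl,C18:1,2.6
0.5 M NaCl,C18:2,5.2
0.5 M NaCl,C18:3n-6,2.6
0.5 M NaCl,C18:3n-3,26.7
0.5 M NaCl,OTHERS,41.1
1.0 M NaCl,C16:0,18.0
1.0 M NaCl,C16:1,2.8
1.0 M NaCl,C18:1,2.3
1.0 M NaCl,C18:2,7.2
1.0 M NaCl,C18:3n-6,3.3
1.0 M NaCl,C18:3n-3,36.9
1.0 M NaCl,OTHERS,29.5
2.0 M NaCl,C14:0,0.5
2.0 M NaCl,C16:0,19.7
2.0 M NaCl,C16:1,2.7
2.0 M NaCl,C18:0,0.9
2.0 M NaCl,C18:1,3.5
2.0 M NaCl,C18:2,10.8
2.0 M NaCl,C18:3n-6,1.8
2.0 M NaCl,C18:3n-3,24.5
2.0 M NaCl,OTHERS,35.6
3.0 M NaCl,C14:0,0.7
3.0 M NaCl,C16:0,20.8
3.0 M NaCl,C16:1,2.9
3.0 M NaCl,C18:0,1.5
3.0 M NaCl,C18:1,3.6
3.0 M NaCl,C18:2,10.1
3.0 M NaCl,C18:3n-6,1.6
3.0 M NaCl,C18:3n-3,27.3
3.0 M NaCl,OTHERS,31.5
4.0 M NaCl,C14:0,0.8
4.0 M NaCl,C16:0,22.9
4.0 M NaCl,C16:1,2.5
4.0 M NaCl,C18:0,1.0
4.0 M NaCl,C18:1,4.2
4.0 M NaCl,C18:2,9.3
4.0 M NaCl,C18:3n-3,28.1
4.0 M NaCl,C22:0,0.4
4.0 M NaCl,OTHERS,30.8
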