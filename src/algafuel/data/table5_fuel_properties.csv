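property,condition,printed
adu,0.5 M NaCl,1.04
adu,1.0 M NaCl,1.40
adu,2.0 M NaCl,1.06
adu,3.0 M NaCl,1.13
adu,4.0 M NaCl,1.09
kv,0.5 M NaCl,4.55
kv,1.0 M NaCl,4.32
kv,2.0 M NaCl,4.53
kv,3.0 M NaCl,4.491
kv,4.0 M NaCl,4.515
rho,0.5 M NaCl,0.87
rho,1.0 M NaCl,0.88
rho,2.0 M NaCl,0.87
rho,3.0 M NaCl,0.87
rho,4.0 M NaCl,0.87
cn,0.5 M NaCl,55.93
cn,1.0 M NaCl,53.53
cn,2.0 M NaCl,55.76
cn,3.0 M NaCl,55.31
cn,4.0 M NaCl,55.56
iv,0.5 M NaCl,90.21
iv,1.0 M NaCl,116.90
iv,2.0 M NaCl,92.06
iv,3.0 M NaCl,97.04
iv,4.0 M NaCl,94.22
fp,0.5 M NaCl,188.09
fp,1.0 M NaCl,184.35
fp,2.0 M NaCl,187.36
fp,3.0 M NaCl,185.42
fp,4.0 M NaCl,186.67
hhv,0.5 M NaCl,40.37
hhv,1.0 M NaCl,41.00
hhv,2.0 M NaCl,40.41
hhv,3.0 M NaCl,40.53
hhv,4.0 M NaCl,40.46
cp,0.5 M NaCl,6.08
cp,1.0 M NaCl,1.24
cp,2.0 M NaCl,5.74
cp,3.0 M NaCl,4.84
cp,4.0 M NaCl,5.35
cfpp,0.5 M NaCl,-9.56
cfpp,1.0 M NaCl,-10.82
cfpp,2.0 M NaCl,-8.87
cfpp,3.0 M NaCl,-4.31
cfpp,4.0 M NaCl,-5.82
os,0.5 M NaCl,6.01
os,1.0 M NaCl,5.07
os,2.0 M NaCl,5.76
os,3.0 M NaCl,5.61
os,4.0 M NaCl,5.74
linolenic,0.5 M NaCl,29.30
linolenic,1.0 M NaCl,40.20
linolenic,2.0 M NaCl,26.30
linolenic,3.0 M NaCl,28.90
linolenic,4.0 M NaCl,28.10
pufa_ge4db,0.5 M NaCl,0
pufa_ge4db,1.0 M NaCl,0
pufa_ge4db,2.0 M NaCl,0
pufa_ge4db,3.0 M NaCl,0
pufa_ge4db,4.0 M NaCl,0
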