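# Reference cells the correlations do not reproduce (apparent print errors
# in the source table). Each is reported as a mismatch by `reproduce-paper`
# together with the value the correlation actually gives, but does not fail
# the run. cp @ 1.0 M: printed 1.24, Eq. on ADU 1.401 gives 1.28.
# cfpp @ 3.0 M: printed -4.31, LCSF 2.83 gives -7.59.
property,condition
cp,1.0 M NaCl
cfpp,3.0 M NaCl
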