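# Example overrides for `algafuel simulate --config ...`.
# Omitted keys keep the default study conditions (five salinities in
# triplicate, 1e6 cells/mL inoculum, 3-day lag, 5 % noise CV).
salinities: [0.5, 1.0, 2.0, 3.0, 4.0]
noise_cv: 0.05
replicates: 3
seed: 0
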