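kappa: 7000.0
kappa_ref: 10000.0
lam: 2.05
r0: 10.0
w_cut: 10.0
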