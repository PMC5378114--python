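# High-density rescue: w0 = K, so early mutants are suppressed until the
# wild type declines to w* = K(1 - dm/bm); w*mu > 1 keeps independence valid.
w0: 10000
K: 10000
alpha: 0.3
bm: 1.3
dm: 1.0
dw: 1.0
mu: 1.0e-3
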