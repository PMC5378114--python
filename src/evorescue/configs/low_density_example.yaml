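# Low-density rescue: carrying capacity well above w0, mutants grow from the
# onset; w0*mu = 1 keeps lineage independence valid.
w0: 10000
K: 110000
alpha: 0.1
bm: 1.3
dm: 1.0
dw: 1.0
mu: 1.0e-4
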