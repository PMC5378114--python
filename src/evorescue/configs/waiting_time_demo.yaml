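# Slow-decline marginal-density scenario used for the waiting-time
# distributions: w0*mu = 1, w0/K exactly at the density boundary.
w0: 10000
K: 110000
alpha: 0.01
bm: 1.1
dm: 1.0
dw: 1.0
mu: 1.0e-4
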