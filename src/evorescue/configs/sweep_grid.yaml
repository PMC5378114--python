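# Default sweep grid: all combinations of decline rate, mutation rate,
# mutant birth rate and carrying capacity, with w0 = 10^4 and dw = dm = 1.
alphas: [0.01, 0.03, 0.1, 0.3, 1.0]
mus: [1.0e-5, 1.0e-4, 1.0e-3]
bms: [1.1, 1.3, 2.0]
Ks: [10000, 110000]
w0: 10000
dm: 1.0
dw: 1.0
n_reps: 200
base_seed: 0
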