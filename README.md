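# evorescue

Stochastic simulation and analytic theory of **evolutionary rescue** — the
race between the extinction of a declining, maladapted population and the
establishment of de-novo beneficial mutations — with a focus on whether
rescue happens through a **hard selective sweep** (one surviving mutant
lineage) or a **soft selective sweep** (several independently arisen
lineages surviving together). It is intended for population geneticists and
modelers studying resistance evolution, conservation genetics, and the
genetic signatures left behind by adaptation under demographic decline.

## Model

A wild-type population of initial size `w0` declines exponentially,
`w(t) = w0 e^{-αt}` with `α = d_w − b_w > 0`. Beneficial mutants arise on
wild-type backgrounds at per-individual rate `μ` and follow a
density-dependent birth–death process:

```
w → w+1 : b_w w          w → w−1 : d_w w
m → m+1 : b_m m [1 − (m+w)/K]     m → m−1 : d_m m
```

Key analytic quantities (all implemented and cross-validated against
simulation):

- **Establishment probability** of a mutant appearing at time τ:
  `p_est(τ) = 2 / (1 + ∫₀^∞ [B+D] exp(−∫₀^t [B−D]) dt)` with
  `B(t) = b_m[1 − w(t)/K]`, `D = d_m`; it rises monotonically to
  `p_∞ = (b_m − d_m)/b_m`.
- **Establishment intensity** `R(t) = w(t) μ p_est(t)`, whose integral Λ is
  the Poisson mean of the number of establishing lineages, giving
  `P_rescue = 1 − e^{−Λ}`, `P_hard = Λ e^{−Λ}`, `P_soft = P_rescue − P_hard`,
  and the sweep-softness law
  `P_soft|rescue = 1 + ((1−P)/P) log(1−P)` — when rescue is likely, it is
  soft.
- **Waiting-time densities** for the first and second establishing lineages,
  `p(τ₁) = R(τ₁) e^{−∫₀^{τ₁} R}` and its second-event analogue.
- **Post-rescue heterozygosity**: the exact hypergeometric probability that
  an n-sample of mutants spans more than one lineage.

The Gillespie simulator tracks every mutant lineage exactly, classifies each
replicate as extinction / hard sweep / soft sweep, and is bit-for-bit
reproducible from a seed.

## Worked example

```python
from evorescue import (make_params, rescue_probabilities, poisson_lambda,
                       run_batch)

params = make_params(w0=10_000, K=110_000, alpha=0.1, bm=1.3, dm=1, dw=1,
                     mu=1e-4)           # low density, w0*mu = 1
theory = rescue_probabilities(params)
print(f"Lambda = {theory.lambda_used:.3f}")
print(f"P_rescue = {theory.p_rescue:.3f}, P_hard = {theory.p_hard:.3f}, "
      f"P_soft = {theory.p_soft:.3f}")
print(f"Poisson approximation: {poisson_lambda(params).p_rescue_approx:.3f}")

batch = run_batch(params, n_reps=300, base_seed=101)
print(f"simulated: extinct {batch.prop_extinction:.3f}, "
      f"hard {batch.prop_hard:.3f}, soft {batch.prop_soft:.3f}")
print(f"mean heterozygosity (n=100 sample): {batch.mean_het[100]:.3f}")
```

prints

```
Lambda = 2.045
P_rescue = 0.871, P_hard = 0.265, P_soft = 0.606
Poisson approximation: 0.950
simulated: extinct 0.157, hard 0.243, soft 0.600
mean heterozygosity (n=100 sample): 0.637
```

Λ ≈ 2 establishing lineages are expected, so rescue is likely (87%) and,
when it happens, it is usually soft — the 300-replicate simulation agrees
with the theory within binomial noise, and the deep-sample heterozygosity
(0.64) tracks the conditional soft-sweep probability
`P_soft/P_rescue ≈ 0.70`. The closed-form Poisson approximation slightly
overestimates rescue, as expected from its use of the asymptotic
establishment probability.

There is also a CLI (`evorescue analytic|simulate|batch|sweep|waiting-times|
fixtures`); `evorescue fixtures` writes the bundled parameter-grid configs.

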