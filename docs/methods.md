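# Methods

## Model and assumptions

The model is a two-type continuous-time birth–death process. Wild-type
individuals are maladapted to the new environment: their per-capita death
rate `d_w` exceeds their birth rate `b_w`, and the decline rate
`α = d_w − b_w > 0` is the single control of demographic collapse (`b_w` is
always derived, never supplied). The wild-type decline is density
*independent* — the deterministic expectation is `w(t) = w0 e^{−αt}` — while
mutant growth is density dependent through the total population size:
`B(t) = b_m [1 − (m + w)/K]`. Consequences worth keeping in mind:

- Early mutants are **not** unconditionally advantageous. If
  `w0/K > 1 − d_m/b_m` (high density), a new mutant is initially
  subcritical and establishment is effectively impossible until the wild
  type declines to `w* = K(1 − d_m/b_m)`, at
  `t* = −(1/α) log(w*/w0)` (clamped to 0 in the low-density case, where the
  formula gives a negative time that plays no role downstream).
- A rescued population equilibrates at `m_eq = K(1 − d_m/b_m)`.
- Mutation is a single-locus, two-allele process at constant per-individual
  rate `μ`, with no back mutation and no standing variation at the onset.
- `d_m = d_w = 1` in all bundled parameter sets (equal expected lifetimes);
  both are free fields.

The analytic layer additionally assumes mutant lineages establish
*independently*: the mutant's own contribution to density is dropped from
the establishment probability. The package flags the regime where this is
expected to fail — population-scale mutation rate below one at the time
establishment becomes possible (`w0 μ < 1` at low density, `w* μ < 1` at
high density) — and the test suite demonstrates the resulting overestimate
of soft sweeps in that regime rather than correcting for it.

## Establishment probability

For a time-inhomogeneous birth–death lineage the establishment probability
of a single mutant appearing at τ is

    p_est(τ) = 2 / (1 + J),
    J = ∫₀^∞ [B(t+τ) + d_m] exp(−ρ(t; τ)) dt,

with the inner (net-growth) integral in closed form,
`ρ(t; τ) = (b_m − d_m) t − c(τ)(1 − e^{−αt})`,
`c(τ) = b_m w(τ)/(K α)`. The closed form is verified against nested numeric
quadrature in the test suite before anything relies on it. Numerical
choices:

- **Log-space evaluation.** In high-density scenarios `exp(−ρ)` spans
  hundreds of orders of magnitude (its peak sits at the density transition).
  The outer integrand is shifted by the minimum of ρ — available in closed
  form — so quadrature operates on O(1) numbers; probabilities below the
  floating-point range underflow cleanly to zero.
- **Truncation + analytic tail.** The outer integral is truncated at
  `max(t* − τ, 0) + 40/(b_m − d_m)` (envelope decayed by e⁻⁴⁰) and an
  exponential tail assuming `B − D = b_m − d_m` beyond the horizon is added.
- Default relative tolerance 1e-8; quadrature that misses its tolerance
  raises rather than returning silently degraded values.
- Tabulated curves default to 400 points, densified geometrically around t*
  where curvature concentrates; the cumulative intensity used by
  waiting-time densities is cached per parameter set.

The expected number of establishments truncates the intensity integral at
`τ_end = log(w0)/α`, the time for the deterministic decline to reach one
individual; waiting-time densities truncate at `log(w0/1000)/α` (10% of 10⁴
individuals). Mass beyond the waiting-time truncation is reported as a
diagnostic, and conditional densities renormalize over the truncated
support.

The closed-form low-density approximation `Λ ≈ w0 μ (b_m − 1)/α` is
implemented exactly in that form. Its premises are `d_m = 1` and `b_m` close
to 1 (so that `p_∞ ≈ b_m − 1`); because it substitutes the *asymptotic*
establishment probability for all t, it always bounds the exact Λ from
above at low density, and its rescue probability can overshoot by
substantially more than a few percent at intermediate Λ (worst around
Λ ≈ 1, or for `b_m = 2` where `b_m − 1 = 2 p_∞`). It is reported only for
low-density parameter sets.

## Simulator

The Gillespie loop draws each waiting time from an exponential with rate
equal to the sum of all event rates at the current state and picks the event
proportionally — exact for the model, since rates depend only on the state.
Design choices:

- **Mutation as conversion**: a mutation event turns one wild-type
  individual into a new lineage of size one (`w → w − 1`), conserving
  individuals per event. The alternative (mutant offspring, w unchanged)
  differs by O(μ) in wild-type dynamics.
- **Rate clamp**: the mutant birth factor is `max(0, 1 − (m+w)/K)` because
  stochastic paths can transiently exceed K.
- **Stopping rules**: extinction (`w = 0` and no mutants) or rescue (total
  mutants ≥ 0.99 m_eq — not fixation; remaining wild-type individuals are
  excluded from heterozygosity). A replicate is a hard sweep if exactly one
  lineage survives to the stopping time, soft if two or more do. Note this
  classifies by the population composition at stopping, so lineages still
  destined to be lost count as survivors, exactly as the outcome is defined.
- **Aggregated rates**: per-lineage rates are summed into total mutant
  birth/death rates; the lineage is chosen proportionally to size only when
  such an event fires, reusing the residual of the event-selection uniform.
- **RNG**: an inline xorshift128+ generator seeded via splitmix64. Identical
  (parameters, seed) pairs reproduce results bit-for-bit; batches derive
  per-replicate seeds from one base seed through `numpy.random.SeedSequence`
  with a counter-style spawn key, and the full seed ledger is retained for
  replay.
- The safety cap of 10⁹ events per replicate aborts (with the seed) rather
  than truncating silently.

The single-lineage Monte-Carlo oracle for p_est uses Lewis–Shedler thinning
instead, which is exact under time-varying rates regardless of step size; a
lineage counts as established once it reaches 500 copies (residual
extinction probability ≤ (d_m/b_m)⁵⁰⁰). It shares nothing with the
quadrature path, making it an independent check.

Simulated establishment times are the *origination* times of lineages that
survive to the stopping time — the intensity R(t) counts origination events
of ultimately-establishing lineages, so this is the measure the analytic
densities describe. Heterozygosity uses the exact without-replacement
(hypergeometric) formula `H = 1 − Σᵢ C(mᵢ,n)/C(M,n)`, evaluated as products
of falling ratios for numerical stability; samples larger than the mutant
population fall back to the whole population.

## What the default experiments emulate — and what they do not

The bundled grid (α ∈ {0.01, 0.03, 0.1, 0.3, 1.0}, μ ∈ {10⁻⁵, 10⁻⁴, 10⁻³},
b_m ∈ {1.1, 1.3, 2.0}, K ∈ {10⁴, 1.1×10⁵}, w0 = 10⁴) spans near-certain
extinction to near-certain soft-sweep rescue, with the two K values giving a
low-density scenario (mutants supercritical from the onset; for b_m = 1.1
the cell sits exactly on the density boundary, treated as low density — w*
= w0 there, so the independence heuristic is unaffected) and a high-density
scenario (w0 = K). These are idealized conditions: single locus, no
standing variation, no linked neutral sites, no population structure,
constant environment after the shift, exponential (not logistic) wild-type
decline. Agreement of theory and simulation here validates the mathematics,
not the realism of any particular biological system.

Replicate presets: "full" scale (1000 per grid cell; 10⁴ for waiting-time
histograms) and "desk" scale (200 per cell; 2000 rescued replicates), the
latter chosen so the whole validation suite runs on a single CPU in minutes.
The test suite uses 300-replicate batches at six independence-valid cells,
which resolves outcome proportions to ±0.03 (one binomial SE).

## Known limitations

- No correction for lineage non-independence: in the slow-decline,
  rare-mutation regime the analytic soft-sweep probability is an
  overestimate (demonstrated, not corrected).
- No τ_k densities beyond the second establishment.
- `log(w0/1000)/α` requires `w0 > 1000`; waiting-time densities refuse
  smaller populations.
- The deterministic-decline truncation τ_end ignores stochasticity in the
  wild-type extinction time; its effect on Λ is below the quadrature
  tolerance for the bundled grid but has not been characterized for extreme
  parameters.
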