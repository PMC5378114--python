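"""Parameter sweeps and simulation-vs-theory experiments.

The default sweep grid covers the extremes of the rescue phenomenology:
five decline rates, three mutation rates, three mutant birth rates and two
carrying capacities (one low-density scenario where mutants grow from the
onset, one high-density scenario where early mutants are suppressed), with
w0 = 10^4 and dw = dm = 1.  Replicate presets: "full" (1000 per cell) and
"desk" (200 per cell, sized for single-CPU validation runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analytics import is_low_density, poisson_lambda, rescue_probabilities
from .establishment import DEFAULT_QUAD, QuadratureOptions
from .gillespie import DEFAULT_HET_SAMPLE_SIZES, run_batch, simulate, replicate_seeds
from .model import RescueParams, derived_quantities, make_params
from .waiting import waiting_time_density

__all__ = [
    "SweepConfig",
    "methods_grid_config",
    "run_sweep",
    "waiting_time_experiment",
    "collect_waiting_times",
]

GRID_ALPHAS = (0.01, 0.03, 0.1, 0.3, 1.0)
GRID_MUS = (1e-5, 1e-4, 1e-3)
GRID_BMS = (1.1, 1.3, 2.0)
GRID_KS = (10_000, 110_000)

REPS_PRESETS = {"full": 1000, "desk": 200}
WAITING_REPS_PRESETS = {"full": 10_000, "desk": 2000}


@dataclass(frozen=True)
class SweepConfig:
    """Grid definition for a sweep over (alpha, mu, bm, K)."""

    alphas: tuple = GRID_ALPHAS
    mus: tuple = GRID_MUS
    bms: tuple = GRID_BMS
    Ks: tuple = GRID_KS
    w0: float = 10_000
    dm: float = 1.0
    dw: float = 1.0
    n_reps: int = REPS_PRESETS["desk"]
    het_sample_sizes: tuple = DEFAULT_HET_SAMPLE_SIZES
    base_seed: int = 0

    def __post_init__(self):
        if not (self.alphas and self.mus and self.bms and self.Ks):
            raise ValueError("sweep grid must be nonempty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def cells(self):
        for K in self.Ks:
            for bm in self.bms:
                for mu in self.mus:
                    for alpha in self.alphas:
                        yield make_params(w0=self.w0, K=K, alpha=alpha, bm=bm,
                                          dm=self.dm, dw=self.dw, mu=mu)


def methods_grid_config(preset: str = "desk", base_seed: int = 0) -> SweepConfig:
    """The full default grid at a named replicate preset."""
    return SweepConfig(n_reps=REPS_PRESETS[preset], base_seed=base_seed)


def run_sweep(config: SweepConfig,
              quad_opts: QuadratureOptions = DEFAULT_QUAD,
              progress=None) -> pd.DataFrame:
    """Run simulation batches and analytic theory over every grid cell.

    Returns one row per cell with inputs, simulated outcome proportions (with
    binomial standard errors), mean heterozygosity, analytic probabilities,
    the low-density Poisson approximation (low-density cells only) and the
    lineage-independence flag.  Failed cells are recorded in the ``error``
    column and do not abort the sweep.
    """
    rows = []
    for i, params in enumerate(config.cells()):
        row = {
            "w0": params.w0, "K": params.K, "alpha": params.alpha,
            "bm": params.bm, "dm": params.dm, "dw": params.dw, "mu": params.mu,
            "error": "",
        }
        try:
            dq = derived_quantities(params)
            theory = rescue_probabilities(params, quad_opts)
            low = is_low_density(params)
            cell_seed = int(replicate_seeds(config.base_seed, 1, stream=i + 1)[0])
            batch = run_batch(params, config.n_reps, cell_seed,
                              het_sample_sizes=config.het_sample_sizes)
            row.update({
                "low_density": low,
                "independence_ok": theory.independence_ok,
                "lambda_exact": theory.lambda_used,
                "p_rescue": theory.p_rescue,
                "p_hard": theory.p_hard,
                "p_soft": theory.p_soft,
                "p_soft_given_rescue": theory.p_soft_given_rescue,
                "n_reps": batch.n_reps,
                "cell_seed": cell_seed,
                "prop_extinction": batch.prop_extinction,
                "prop_hard": batch.prop_hard,
                "prop_soft": batch.prop_soft,
                "se_extinction": batch.se_extinction,
                "se_hard": batch.se_hard,
                "se_soft": batch.se_soft,
                "n_rescued": batch.n_rescued,
                "pop_scale_mut_onset": dq.pop_scale_mut_onset,
                "pop_scale_mut_star": dq.pop_scale_mut_star,
            })
            for n in config.het_sample_sizes:
                row[f"mean_het_{n}"] = batch.mean_het[n]
            if low:
                approx = poisson_lambda(params)
                row["lambda_poisson"] = approx.lam
                row["p_rescue_poisson"] = approx.p_rescue_approx
                row["p_soft_poisson"] = approx.p_soft_approx
            else:
                row["lambda_poisson"] = math.nan
                row["p_rescue_poisson"] = math.nan
                row["p_soft_poisson"] = math.nan
        except Exception as exc:  # keep sweeping; record the failure
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        if progress is not None:
            progress(i, row)
    return pd.DataFrame(rows)


def collect_waiting_times(params: RescueParams, n_rescued: int, base_seed: int,
                          rescue_floor: float = 1e-3, max_attempts_factor: int = 20):
    """Simulate until ``n_rescued`` rescued replicates are collected.

    Returns (tau1, tau2, n_attempted): origination times of the first and
    second surviving lineage per rescued replicate (tau2 is NaN for hard
    sweeps).  Aborts if the running rescue rate falls below ``rescue_floor``.
    """
    tau1, tau2 = [], []
    max_attempts = int(n_rescued / rescue_floor) + n_rescued * max_attempts_factor
    seeds = replicate_seeds(base_seed, max_attempts)
    attempted = 0
    for s in seeds:
        if len(tau1) >= n_rescued:
            break
        attempted += 1
        res = simulate(params, int(s))
        if res.outcome == "extinction":
            if attempted >= 500 and len(tau1) / attempted < rescue_floor:
                raise RuntimeError(
                    f"rescue rate below floor {rescue_floor:g} after {attempted} "
                    "replicates; waiting-time collection infeasible")
            continue
        origins = sorted(res.lineage_origins)
        tau1.append(origins[0])
        tau2.append(origins[1] if len(origins) > 1 else math.nan)
    if len(tau1) < n_rescued:
        raise RuntimeError(
            f"collected only {len(tau1)}/{n_rescued} rescued replicates "
            f"within {max_attempts} attempts")
    return np.array(tau1), np.array(tau2), attempted


def waiting_time_experiment(params: RescueParams, n_reps: int, base_seed: int,
                            n_bins: int = 40,
                            quad_opts: QuadratureOptions = DEFAULT_QUAD) -> pd.DataFrame:
    """Empirical vs analytic waiting-time densities for tau1 and tau2.

    Simulates until ``n_reps`` rescued replicates are collected, histograms
    the origination times of the first and second surviving lineages and
    tabulates them against the conditional analytic densities.
    """
    tau1, tau2, _ = collect_waiting_times(params, n_reps, base_seed)
    d1 = waiting_time_density(params, 1, quad_opts, conditional=True)
    d2 = waiting_time_density(params, 2, quad_opts, conditional=True)
    support = d1.times[-1]
    edges = np.linspace(0.0, support, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    h1, _ = np.histogram(tau1, bins=edges, density=True)
    t2 = tau2[~np.isnan(tau2)]
    h2, _ = np.histogram(t2, bins=edges, density=True)
    return pd.DataFrame({
        "time": centers,
        "empirical_tau1": h1,
        "analytic_tau1": np.interp(centers, d1.times, d1.density),
        "empirical_tau2": h2,
        "analytic_tau2": np.interp(centers, d2.times, d2.density),
    })
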