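"""Exact stochastic simulation of the rescue model with lineage tracking.

Each replicate runs the event-driven birth-death process with transition
rates

    w -> w+1 : bw*w          w -> w-1 : dw*w
    m -> m+1 : bm*m*[1-(m+w)/K]   m -> m-1 : dm*m
    mutation : mu*w   (one wild-type individual converts into a new mutant
                       lineage of size one)

until either the whole population is gone (extinction) or the mutant
subpopulation reaches 99% of its equilibrium size m_eq = K(1 - dm/bm)
(rescue).  A rescue is classified as a hard sweep when exactly one mutant
lineage survives to the stopping time and as a soft sweep when two or more
do.  The density factor is clamped at zero because stochastic paths can
transiently exceed K.

Heterozygosity of a rescued population is the probability that a
without-replacement sample of n mutants does not come entirely from a single
lineage (identity by descent = same mutational origin):

    H = 1 - sum_i C(m_i, n) / C(M, n),   M = sum_i m_i.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .model import RescueParams, derived_quantities

__all__ = [
    "SimulationResult",
    "BatchSummary",
    "simulate",
    "run_batch",
    "heterozygosity",
    "mc_establishment_probability",
    "replicate_seeds",
    "append_replicate_log",
]

_LOG_COLUMNS = ("seed", "outcome", "final_time", "n_lineages",
                "total_mutants", "wild_count", "n_mutations")

DEFAULT_MAX_EVENTS = 10 ** 9
DEFAULT_HET_SAMPLE_SIZES = (2, 100)


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of one Gillespie replicate."""

    outcome: str                    # "extinction" | "hard" | "soft"
    final_time: float
    wild_count: int
    lineage_sizes: tuple[int, ...]      # surviving mutant lineages
    lineage_origins: tuple[float, ...]  # origination time of each
    n_mutations: int
    seed: int

    @property
    def total_mutants(self) -> int:
        return sum(self.lineage_sizes)


@dataclass(frozen=True)
class BatchSummary:
    """Aggregate over independent replicates of one parameter set."""

    params: RescueParams
    n_reps: int
    prop_extinction: float
    prop_hard: float
    prop_soft: float
    se_extinction: float
    se_hard: float
    se_soft: float
    mean_het: dict            # sample size n -> mean heterozygosity over rescued reps
    se_het: dict              # sample size n -> standard error of that mean
    n_rescued: int
    seeds: tuple[int, ...]
    base_seed: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "params": {k: getattr(self.params, k)
                       for k in ("w0", "K", "alpha", "bm", "dm", "dw", "mu")},
            "n_reps": self.n_reps,
            "base_seed": self.base_seed,
            "prop_extinction": self.prop_extinction,
            "prop_hard": self.prop_hard,
            "prop_soft": self.prop_soft,
            "se_extinction": self.se_extinction,
            "se_hard": self.se_hard,
            "se_soft": self.se_soft,
            "mean_het": {str(k): v for k, v in self.mean_het.items()},
            "se_het": {str(k): v for k, v in self.se_het.items()},
            "n_rescued": self.n_rescued,
            "seeds": list(self.seeds),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def append_replicate_log(path, result: SimulationResult) -> None:
    """Append one replicate as a TSV row (header written on first use)."""
    import os

    new_file = not os.path.exists(path) or os.path.getsize(path) == 0
    with open(path, "a") as fh:
        if new_file:
            fh.write("\t".join(_LOG_COLUMNS) + "\n")
        fh.write("\t".join(str(v) for v in (
            result.seed, result.outcome, result.final_time,
            len(result.lineage_sizes), result.total_mutants,
            result.wild_count, result.n_mutations)) + "\n")


def replicate_seeds(base_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Counter-based per-replicate seeds derived from one base seed."""
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(stream),))
    return ss.generate_state(n, dtype=np.uint32)


def simulate(params: RescueParams, seed: int,
             max_events: int = DEFAULT_MAX_EVENTS,
             _checkpoints: np.ndarray | None = None):
    """Run one replicate; returns a :class:`SimulationResult`.

    Identical (params, seed) pairs reproduce identical results bit-for-bit.
    ``_checkpoints`` optionally records the wild-type count at given times
    (used to validate the event loop against the deterministic decay); when
    provided the return value is (result, w_at_checkpoints).
    """
    dq = derived_quantities(params)
    m_stop = 0.99 * dq.m_eq
    chk = np.empty(0, dtype=np.float64) if _checkpoints is None \
        else np.asarray(_checkpoints, dtype=np.float64)
    status, t, w, sizes, origins, n_mut, n_events, w_chk = _engine.run_rescue(
        int(params.w0), float(params.K), params.alpha, params.bm, params.dm,
        params.dw, params.mu, float(m_stop), int(seed) & 0xFFFFFFFF,
        int(max_events), chk)
    if status == _engine.STATUS_EVENT_CAP:
        raise RuntimeError(
            f"simulation exceeded the event cap ({max_events}) without terminating "
            f"(seed={seed})")
    if status == _engine.STATUS_EXTINCTION:
        outcome = "extinction"
    else:
        outcome = "hard" if len(sizes) == 1 else "soft"
    result = SimulationResult(
        outcome=outcome,
        final_time=float(t),
        wild_count=int(w),
        lineage_sizes=tuple(int(s) for s in sizes),
        lineage_origins=tuple(float(o) for o in origins),
        n_mutations=int(n_mut),
        seed=int(seed),
    )
    if _checkpoints is not None:
        return result, w_chk
    return result


def heterozygosity(lineage_sizes, n: int) -> float:
    """Probability that n mutants sampled without replacement span >1 lineage.

    Exact hypergeometric evaluation via products of falling ratios; when n
    exceeds the total mutant count M the whole population is sampled (n = M).
    """
    sizes = [int(s) for s in lineage_sizes if s > 0]
    if not sizes:
        raise ValueError("lineage_sizes must contain at least one nonempty lineage")
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    M = sum(sizes)
    n = min(n, M)
    if n < 2:
        return 0.0  # single mutant individual: nothing to compare
    prob_same = 0.0
    for m_i in sizes:
        if m_i < n:
            continue
        term = 1.0
        for j in range(n):
            term *= (m_i - j) / (M - j)
        prob_same += term
    return min(max(1.0 - prob_same, 0.0), 1.0)


def run_batch(params: RescueParams, n_reps: int, base_seed: int,
              het_sample_sizes=DEFAULT_HET_SAMPLE_SIZES,
              max_events: int = DEFAULT_MAX_EVENTS) -> BatchSummary:
    """Run ``n_reps`` independent replicates and aggregate the outcomes."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = replicate_seeds(base_seed, n_reps)
    counts = {"extinction": 0, "hard": 0, "soft": 0}
    het_vals = {n: [] for n in het_sample_sizes}
    for s in seeds:
        try:
            res = simulate(params, int(s), max_events=max_events)
        except RuntimeError as exc:
            raise RuntimeError(f"replicate with seed {int(s)} failed: {exc}") from exc
        counts[res.outcome] += 1
        if res.outcome != "extinction":
            for n in het_sample_sizes:
                het_vals[n].append(heterozygosity(res.lineage_sizes, n))
    n_rescued = counts["hard"] + counts["soft"]

    def _prop_se(c):
        p = c / n_reps
        return p, math.sqrt(p * (1.0 - p) / n_reps)

    def _mean_se(vals):
        if not vals:
            return float("nan"), float("nan")
        arr = np.asarray(vals)
        mean = float(arr.mean())
        se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else float("nan")
        return mean, se

    p_ext, se_ext = _prop_se(counts["extinction"])
    p_hard, se_hard = _prop_se(counts["hard"])
    p_soft, se_soft = _prop_se(counts["soft"])
    het_stats = {n: _mean_se(het_vals[n]) for n in het_sample_sizes}
    return BatchSummary(
        params=params, n_reps=n_reps,
        prop_extinction=p_ext, prop_hard=p_hard, prop_soft=p_soft,
        se_extinction=se_ext, se_hard=se_hard, se_soft=se_soft,
        mean_het={n: v[0] for n, v in het_stats.items()},
        se_het={n: v[1] for n, v in het_stats.items()},
        n_rescued=n_rescued,
        seeds=tuple(int(s) for s in seeds), base_seed=int(base_seed),
    )


def mc_establishment_probability(params: RescueParams, tau: float, n_lineages: int,
                                 seed: int, m_est: int = 500):
    """Monte-Carlo establishment probability for a lineage appearing at ``tau``.

    Simulates ``n_lineages`` independent single-mutant lineages under the
    time-varying rates (exact thinning; the mutant's own density contribution
    is excluded, matching the analytic assumption) and counts those reaching
    ``m_est`` copies -- at which point ultimate extinction odds are
    negligible for any supercritical endpoint.  Returns (p_hat, se).
    """
    n_success = _engine.lineage_establishment_mc(
        int(n_lineages), float(tau), float(params.w0), float(params.K),
        params.alpha, params.bm, params.dm, int(m_est), int(seed) & 0xFFFFFFFF)
    p_hat = n_success / n_lineages
    se = math.sqrt(max(p_hat * (1.0 - p_hat), 1.0 / n_lineages) / n_lineages)
    return p_hat, se
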