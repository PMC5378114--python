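"""Probabilities of rescue, hard sweeps and soft sweeps.

Mutant establishments form a time-inhomogeneous Poisson process with mean
Lambda = int_0^tau_end R(t) dt, so (assuming independent lineages)

    P_rescue = 1 - exp(-Lambda)          (at least one establishment)
    P_hard   = Lambda * exp(-Lambda)     (exactly one: a hard sweep)
    P_soft   = P_rescue - P_hard         (two or more: a soft sweep)

Eliminating Lambda gives the sweep-softness law used throughout:
P_soft|rescue = 1 + ((1-P)/P) log(1-P) with P = P_rescue, monotonically
increasing on (0, 1) -- when rescue is likely it is driven by soft sweeps.

A closed-form approximation for low-density scenarios treats the
establishment probability as its asymptote bm - 1 (valid for dm = 1 and bm
close to 1): the wild type contributes w0/alpha individual-time-units before
extinction, giving Lambda ~= w0 * mu * (bm - 1) / alpha.

The lineage-independence assumption behind all of this holds when mutations
are common while establishment is possible: w0*mu >= 1 in low-density
scenarios and w_star*mu >= 1 in high-density scenarios (where establishment
only becomes likely once the wild type has declined to w_star).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .establishment import DEFAULT_QUAD, QuadratureOptions, expected_establishments
from .model import RescueParams, derived_quantities

__all__ = [
    "RescueProbabilities",
    "PoissonApprox",
    "rescue_probabilities",
    "poisson_lambda",
    "psoft_given_rescue",
    "is_low_density",
    "independence_ok",
]


@dataclass(frozen=True)
class RescueProbabilities:
    p_rescue: float
    p_hard: float
    p_soft: float
    p_soft_given_rescue: float
    lambda_used: float
    independence_ok: bool


@dataclass(frozen=True)
class PoissonApprox:
    lam: float
    p_rescue_approx: float
    p_soft_approx: float


def is_low_density(params: RescueParams) -> bool:
    """True when w0/K <= 1 - dm/bm, i.e. early mutants grow from the onset.

    The boundary case (equality) is classified as low density; there
    w_star = w0 so the independence heuristic is identical either way.
    """
    return params.w0 / params.K <= 1.0 - params.dm / params.bm


def independence_ok(params: RescueParams) -> bool:
    """Population-scale mutation-rate heuristic for lineage independence."""
    dq = derived_quantities(params)
    scale = dq.pop_scale_mut_onset if is_low_density(params) else dq.pop_scale_mut_star
    return scale >= 1.0


def rescue_probabilities(params: RescueParams,
                         quad_opts: QuadratureOptions = DEFAULT_QUAD) -> RescueProbabilities:
    """Exact-Poisson rescue/hard/soft probabilities from the intensity integral."""
    lam = expected_establishments(params, quad_opts)
    p_rescue = -math.expm1(-lam)
    p_hard = lam * math.exp(-lam)
    p_soft = max(p_rescue - p_hard, 0.0)
    return RescueProbabilities(
        p_rescue=p_rescue,
        p_hard=p_hard,
        p_soft=p_soft,
        p_soft_given_rescue=psoft_given_rescue(p_rescue),
        lambda_used=lam,
        independence_ok=independence_ok(params),
    )


def poisson_lambda(params: RescueParams) -> PoissonApprox:
    """Low-density approximation Lambda = w0 * mu * (bm - 1) / alpha.

    Assumes dm = 1 and bm not much above 1, so the establishment probability
    is approximated by its asymptote bm - 1 for all t; warns outside the
    low-density regime where the premise fails badly.
    """
    if not is_low_density(params):
        warnings.warn(
            "poisson_lambda assumes a low-density scenario (w0/K <= 1 - dm/bm); "
            "the approximation overestimates badly at high density",
            stacklevel=2,
        )
    lam = params.w0 * params.mu * (params.bm - 1.0) / params.alpha
    p_rescue = -math.expm1(-lam)
    p_soft = max(p_rescue - lam * math.exp(-lam), 0.0)
    return PoissonApprox(lam=lam, p_rescue_approx=p_rescue, p_soft_approx=p_soft)


def psoft_given_rescue(p_rescue: float) -> float:
    """Probability a rescue is soft, as a function of the rescue probability.

    1 + ((1 - p)/p) * log(1 - p), continuously extended to 0 at p = 0 and 1
    at p = 1.
    """
    if not 0.0 <= p_rescue <= 1.0:
        raise ValueError("p_rescue must lie in [0, 1]")
    if p_rescue == 0.0:
        return 0.0
    if p_rescue == 1.0:
        return 1.0
    return 1.0 + (1.0 - p_rescue) / p_rescue * math.log1p(-p_rescue)
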