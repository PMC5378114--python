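"""Parameters and closed-form derived quantities of the rescue model.

The model: a maladapted wild-type population of initial size ``w0`` declines
exponentially at per-capita rate ``alpha = dw - bw > 0`` after an environmental
shift.  Beneficial mutants appear on wild-type backgrounds at per-individual
rate ``mu`` and grow logistically toward a carrying capacity ``K`` with
maximal per-capita birth rate ``bm`` and death rate ``dm``.  Rescue occurs if
at least one mutant lineage establishes before the wild type goes extinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping

__all__ = [
    "RescueParams",
    "DerivedQuantities",
    "make_params",
    "wild_type_size",
    "derived_quantities",
    "params_to_config",
    "params_from_config",
]

_FIELDS = ("w0", "K", "alpha", "bm", "dm", "dw", "mu")


@dataclass(frozen=True)
class RescueParams:
    """Validated parameter set.

    Attributes
    ----------
    w0 : initial wild-type population size (individuals).
    K : carrying capacity setting the scale of density dependence.
    alpha : wild-type per-capita decline rate (per unit time).
    bm : mutant maximal per-capita birth rate at zero density.
    dm : mutant per-capita death rate.
    dw : wild-type per-capita death rate.
    mu : per-individual beneficial mutation rate (per unit time).
    """

    w0: float
    K: float
    alpha: float
    bm: float
    dm: float
    dw: float
    mu: float

    @property
    def bw(self) -> float:
        """Wild-type per-capita birth rate, derived as ``dw - alpha``."""
        return self.dw - self.alpha


@dataclass(frozen=True)
class DerivedQuantities:
    """Closed-form quantities derived from a :class:`RescueParams`.

    ``m_eq``  -- mutant equilibrium size K(1 - dm/bm).
    ``w_star`` -- wild-type size at which the mutant growth rate changes sign
                  (same expression as ``m_eq`` in this model).
    ``t_star`` -- time at which w(t) crosses ``w_star`` (clamped to 0 when the
                  crossing predates the decline, i.e. the low-density case).
    ``p_inf`` -- asymptotic establishment probability (bm - dm)/bm.
    ``tau_end`` -- time for the deterministic wild-type decline to reach one
                  individual, log(w0)/alpha.
    ``tau_end_10pct`` -- time to reach 10% of 10^4 individuals as printed,
                  log(w0/1000)/alpha; positive only for w0 > 1000.
    ``pop_scale_mut_onset`` -- population-scale mutation rate w0*mu at onset.
    ``pop_scale_mut_star`` -- population-scale mutation rate w_star*mu at the
                  density transition.
    """

    m_eq: float
    w_star: float
    t_star: float
    p_inf: float
    tau_end: float
    tau_end_10pct: float
    pop_scale_mut_onset: float
    pop_scale_mut_star: float


def make_params(
    w0: float,
    K: float,
    alpha: float,
    bm: float,
    dm: float = 1.0,
    dw: float = 1.0,
    mu: float = 0.0,
) -> RescueParams:
    """Validate and build a :class:`RescueParams`.

    Raises
    ------
    ValueError
        If ``bm <= dm`` (no viable mutant: rescue is impossible and the
        equilibrium size is undefined), if ``alpha <= 0`` (wild type not
        declining), if ``alpha > dw`` (implied negative wild-type birth
        rate), or if any argument is negative or non-finite.
    """
    vals = dict(w0=w0, K=K, alpha=alpha, bm=bm, dm=dm, dw=dw, mu=mu)
    for name, v in vals.items():
        v = float(v)
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and nonnegative, got {v!r}")
        vals[name] = v
    if vals["alpha"] <= 0:
        raise ValueError("alpha must be > 0: the wild type must be strictly declining")
    if vals["bm"] <= vals["dm"]:
        raise ValueError(
            "bm must exceed dm: otherwise no viable mutant exists, rescue is "
            "impossible and m_eq is undefined"
        )
    if vals["alpha"] > vals["dw"]:
        raise ValueError("alpha must not exceed dw (wild-type birth rate bw = dw - alpha >= 0)")
    if vals["w0"] < 1:
        raise ValueError("w0 must be at least 1")
    if vals["K"] < 1:
        raise ValueError("K must be at least 1")
    return RescueParams(**vals)


def wild_type_size(params: RescueParams, t: float) -> float:
    """Deterministic wild-type size w(t) = w0 * exp(-alpha * t)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return params.w0 * math.exp(-params.alpha * t)


def derived_quantities(params: RescueParams) -> DerivedQuantities:
    """Evaluate all closed-form derived quantities for ``params``."""
    p = params
    m_eq = p.K * (1.0 - p.dm / p.bm)
    w_star = m_eq
    # time at which w(t) = w_star; negative (clamped to 0) when w0 <= w_star
    t_star = -math.log(w_star / p.w0) / p.alpha
    t_star = max(t_star, 0.0)
    p_inf = (p.bm - p.dm) / p.bm
    tau_end = math.log(p.w0) / p.alpha
    tau_end_10pct = math.log(p.w0 / 1000.0) / p.alpha
    return DerivedQuantities(
        m_eq=m_eq,
        w_star=w_star,
        t_star=t_star,
        p_inf=p_inf,
        tau_end=tau_end,
        tau_end_10pct=tau_end_10pct,
        pop_scale_mut_onset=p.w0 * p.mu,
        pop_scale_mut_star=w_star * p.mu,
    )


def params_to_config(params: RescueParams) -> dict:
    """Flat ``{field: value}`` mapping suitable for YAML serialization."""
    return asdict(params)


def params_from_config(config: Mapping) -> RescueParams:
    """Build validated params from a flat mapping with the canonical field names."""
    unknown = set(config) - set(_FIELDS)
    if unknown:
        raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
    missing = {"w0", "K", "alpha", "bm"} - set(config)
    if missing:
        raise ValueError(f"missing required parameter fields: {sorted(missing)}")
    return make_params(**{k: config[k] for k in _FIELDS if k in config})
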