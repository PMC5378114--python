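"""Waiting-time densities for the first and second establishing lineages.

With establishments forming an inhomogeneous Poisson process of intensity
R(t), the first establishment time tau_1 has (unconditional) density

    p(tau_1) = R(tau_1) * exp(-int_0^tau_1 R dt),

which integrates over [0, inf) to P_rescue, and the second establishment time
has density

    p(tau_2) = int_0^tau_2 p(tau_1) R(tau_2) exp(-int_{tau_1}^{tau_2} R dt) dtau_1,

integrating to P(k >= 2).  Densities are tabulated on [0, tau_end_10pct]
(the time for the deterministic decline to reach 10% of 10^4 individuals);
mass beyond the truncation is reported as a diagnostic, and conditional
densities -- conditioned on rescue (order 1) or on at least two
establishments (order 2) -- are renormalized over the truncated support.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .establishment import DEFAULT_QUAD, QuadratureOptions, intensity_curve
from .model import RescueParams, derived_quantities

__all__ = [
    "WaitingTimeDensity",
    "density_tau1",
    "density_tau2",
    "waiting_time_density",
    "sample_waiting_time",
]


@dataclass(frozen=True)
class WaitingTimeDensity:
    """Tabulated waiting-time density for the k-th establishment (k = order)."""

    params: RescueParams
    order: int
    times: np.ndarray
    density: np.ndarray
    conditional: bool
    mass: float        # integral of the unconditional density over the support
    tail_mass: float   # unconditional mass beyond the truncation (diagnostic)

    def mean(self) -> float:
        """First moment of the tabulated (conditional) density."""
        norm = trapezoid(self.density, self.times)
        return trapezoid(self.times * self.density, self.times) / norm

    def cdf(self) -> np.ndarray:
        c = np.concatenate([[0.0], cumulative_trapezoid(self.density, self.times)])
        return c

    def to_tsv(self, path, sidecar_path=None) -> None:
        p = self.params
        header = (f"# waiting-time density order={self.order} conditional={self.conditional} "
                  f"w0={p.w0:g} K={p.K:g} alpha={p.alpha:g} bm={p.bm:g} dm={p.dm:g} mu={p.mu:g}"
                  "\ntime\tdensity")
        np.savetxt(path, np.column_stack([self.times, self.density]),
                   delimiter="\t", header=header, comments="")
        if sidecar_path is not None:
            meta = {
                "order": self.order,
                "conditional": self.conditional,
                "normalization_mass": self.mass,
                "truncation_mass": self.tail_mass,
                "params": {k: getattr(p, k) for k in ("w0", "K", "alpha", "bm", "dm", "dw", "mu")},
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def density_tau1(params: RescueParams, tau1: float,
                 quad_opts: QuadratureOptions = DEFAULT_QUAD) -> float:
    """Unconditional density of the first establishment time at ``tau1``.

    Uses the cached cumulative intensity grid for int_0^tau R dt and an exact
    intensity evaluation at ``tau1``.
    """
    if tau1 < 0:
        raise ValueError("tau1 must be >= 0")
    if params.mu == 0.0:
        return 0.0
    curve = intensity_curve(params, quad_opts)
    R = float(np.interp(tau1, curve.times, curve.R))
    return R * math.exp(-float(curve.cumulative(tau1)))


def density_tau2(params: RescueParams, tau2: float,
                 quad_opts: QuadratureOptions = DEFAULT_QUAD) -> float:
    """Unconditional density of the second establishment time at ``tau2``.

    Nested integral over all first-establishment times tau_1 < tau_2,
    evaluated by trapezoidal quadrature over the cached cumulative-intensity
    grid (O(grid) per evaluation).
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    if params.mu == 0.0 or tau2 == 0.0:
        return 0.0
    curve = intensity_curve(params, quad_opts)
    mask = curve.times < tau2
    t1 = np.concatenate([curve.times[mask], [tau2]])
    R1 = np.concatenate([curve.R[mask], [float(np.interp(tau2, curve.times, curve.R))]])
    cum1 = np.concatenate([curve.cum_R[mask], [float(curve.cumulative(tau2))]])
    R2 = R1[-1]
    cum2 = cum1[-1]
    # p(tau1) * exp(-(Lambda(tau2) - Lambda(tau1))) = R(tau1) exp(-Lambda(tau2))
    integrand = R1 * np.exp(-cum1) * R2 * np.exp(-(cum2 - cum1))
    return float(trapezoid(integrand, t1))


def waiting_time_density(params: RescueParams, order: int,
                         quad_opts: QuadratureOptions = DEFAULT_QUAD,
                         conditional: bool = True) -> WaitingTimeDensity:
    """Tabulate the order-1 or order-2 waiting-time density on the truncated support."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    dq = derived_quantities(params)
    trunc = dq.tau_end_10pct
    if trunc <= 0:
        raise ValueError("truncated support is empty: requires w0 > 1000")
    fn = density_tau1 if order == 1 else density_tau2
    times = np.linspace(0.0, trunc, quad_opts.grid_size)
    dens = np.array([fn(params, float(t), quad_opts) for t in times])
    mass = float(trapezoid(dens, times))

    # total unconditional mass over [0, inf): P(k>=1) or P(k>=2) at Lambda_exact
    lam = intensity_curve(params, quad_opts).Lambda_exact
    if order == 1:
        total = -math.expm1(-lam)
    else:
        total = -math.expm1(-lam) - lam * math.exp(-lam)
    tail = max(total - mass, 0.0)

    if conditional:
        dens = dens / mass if mass > 0 else dens
    return WaitingTimeDensity(params=params, order=order, times=times, density=dens,
                              conditional=conditional, mass=mass, tail_mass=tail)


def sample_waiting_time(density: WaitingTimeDensity, rng_seed, size: int | None = None):
    """Inverse-CDF draws from a tabulated conditional density.

    Raises if the density is not conditional or its grid mass is not ~1.
    """
    if not density.conditional:
        raise ValueError("sampling requires a conditional (normalized) density")
    cdf = density.cdf()
    total = cdf[-1]
    if not math.isclose(total, 1.0, abs_tol=1e-3):
        raise ValueError(f"density is not normalized on its grid (mass={total:g})")
    cdf = cdf / total
    rng = np.random.default_rng(rng_seed)
    u = rng.random(size if size is not None else 1)
    draws = np.interp(u, cdf, density.times)
    return draws if size is not None else float(draws[0])
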