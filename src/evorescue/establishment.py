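"""Time-dependent establishment probability and establishment intensity.

A single mutant appearing at time ``tau`` experiences per-capita birth rate
``B(t) = bm * (1 - w(t)/K)`` (the declining wild type relaxes the density
restriction over time) and constant death rate ``D(t) = dm``.  For such a
time-inhomogeneous birth-death process the probability of establishment --
survival past stochastic loss at low copy number -- is

    p_est(tau) = 2 / (1 + J(tau)),
    J(tau) = int_0^inf [B(t+tau) + dm] * exp(-rho(t; tau)) dt,
    rho(t; tau) = int_0^t [B(t'+tau) - dm] dt'.

The inner integral has the closed form

    rho(t; tau) = (bm - dm) * t - c(tau) * (1 - exp(-alpha * t)),
    c(tau) = bm * w(tau) / (K * alpha),

which this module uses after verification against nested quadrature (see the
test suite).  The outer integral is evaluated adaptively in shifted log space
(exp(-rho) can exceed the floating-point range by hundreds of orders of
magnitude in high-density scenarios) and truncated at a horizon past which an
analytic exponential tail is added.

The establishment intensity R(t) = w(t) * mu * p_est(t) is the rate at which
ultimately-establishing mutant lineages are generated; its integral Lambda is
the mean of the Poisson number of establishments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad, cumulative_trapezoid

from .model import RescueParams, derived_quantities, wild_type_size

__all__ = [
    "QuadratureOptions",
    "EstablishmentCurve",
    "IntensityCurve",
    "QuadratureError",
    "p_establish",
    "p_infinity",
    "intensity",
    "expected_establishments",
    "establishment_curve",
    "intensity_curve",
]

_LOG_HUGE = 700.0  # beyond this, 2/(1+e^x) underflows; switch to 2*e^(-x)


class QuadratureError(RuntimeError):
    """Adaptive quadrature failed to reach the requested tolerance."""


@dataclass(frozen=True)
class QuadratureOptions:
    """Numerical settings for the establishment-probability integrals.

    rel_tol : relative tolerance for adaptive quadrature.
    outer_horizon : truncation time for the outer integral, measured from the
        mutant's appearance time.  ``None`` (default) chooses
        ``max(t_star - tau, 0) + 40/(bm - dm)``, by which point the integrand
        envelope has decayed by e^-40; an analytic exponential tail assuming
        B - D = bm - dm beyond the horizon is always added.
    grid_size : number of points for tabulated curves.
    """

    rel_tol: float = 1e-8
    outer_horizon: float | None = None
    grid_size: int = 400

    def __post_init__(self):
        if not (0.0 < self.rel_tol < 1.0):
            raise ValueError("rel_tol must be in (0, 1)")
        if self.outer_horizon is not None and self.outer_horizon <= 0:
            raise ValueError("outer_horizon must be > 0")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")


DEFAULT_QUAD = QuadratureOptions()


@dataclass(frozen=True)
class EstablishmentCurve:
    """p_est tabulated on an ascending time grid."""

    params: RescueParams
    times: np.ndarray
    p_est: np.ndarray

    def to_tsv(self, path) -> None:
        header = "# p_est for " + _param_tag(self.params) + "\ntime\tp_est"
        np.savetxt(path, np.column_stack([self.times, self.p_est]),
                   delimiter="\t", header=header, comments="")


@dataclass(frozen=True)
class IntensityCurve:
    """R(t) = w(t) mu p_est(t) tabulated on a grid with cumulative integral.

    ``cum_R[i]`` approximates int_0^times[i] R dt; ``Lambda_exact`` is the
    adaptive-quadrature integral of R over [0, tau_end], the expected number
    of establishments (the Poisson mean of the realized number k).
    """

    params: RescueParams
    times: np.ndarray
    R: np.ndarray
    cum_R: np.ndarray
    Lambda_exact: float

    def cumulative(self, t) -> np.ndarray:
        """Interpolated cumulative intensity int_0^t R dt (flat beyond grid)."""
        return np.interp(t, self.times, self.cum_R)

    def to_tsv(self, path) -> None:
        header = "# intensity R(t) for " + _param_tag(self.params) + "\ntime\tR"
        np.savetxt(path, np.column_stack([self.times, self.R]),
                   delimiter="\t", header=header, comments="")


def _param_tag(p: RescueParams) -> str:
    return (f"w0={p.w0:g} K={p.K:g} alpha={p.alpha:g} bm={p.bm:g} "
            f"dm={p.dm:g} dw={p.dw:g} mu={p.mu:g}")


def p_infinity(params: RescueParams) -> float:
    """Asymptotic establishment probability (bm - dm)/bm.

    Independent of K and alpha: the wild type eventually goes extinct, leaving
    a constant-rate supercritical birth-death process with survival odds
    (bm - dm) : dm per the classic branching-process result.
    """
    return (params.bm - params.dm) / params.bm


def _quad_checked(f, a, b, rel_tol):
    if b <= a:
        return 0.0
    val, err = quad(f, a, b, epsrel=rel_tol, epsabs=0.0, limit=200)
    if err > rel_tol * abs(val) + 1e-13:
        raise QuadratureError(
            f"outer integral did not converge: value={val:g}, abserr={err:g}")
    return val


def _log_denominator(params: RescueParams, tau: float, opts: QuadratureOptions) -> float:
    """log J(tau) for p_est(tau) = 2/(1 + J(tau)), computed in shifted space."""
    p = params
    s = p.bm - p.dm
    w_tau = p.w0 * math.exp(-p.alpha * tau)
    c = p.bm * w_tau / (p.K * p.alpha)

    def rho(t):
        return s * t - c * (-math.expm1(-p.alpha * t))

    # rho decreases while B < D; its minimum sits at the density transition
    if c * p.alpha > s:
        t_c = math.log(c * p.alpha / s) / p.alpha
    else:
        t_c = 0.0
    rho_min = rho(t_c)

    horizon = opts.outer_horizon if opts.outer_horizon is not None else t_c + 40.0 / s

    def integrand(t):
        B = p.bm * (1.0 - w_tau * math.exp(-p.alpha * t) / p.K)
        return (B + p.dm) * math.exp(-(rho(t) - rho_min))

    body = (_quad_checked(integrand, 0.0, t_c, opts.rel_tol)
            + _quad_checked(integrand, t_c, horizon, opts.rel_tol))
    # analytic tail: B ~ bm, rho grows linearly at slope s beyond the horizon
    tail = (p.bm + p.dm) / s * math.exp(-(rho(horizon) - rho_min))
    return -rho_min + math.log(body + tail)


def p_establish(params: RescueParams, tau: float,
                quad_opts: QuadratureOptions = DEFAULT_QUAD) -> float:
    """Establishment probability for a single mutant appearing at time ``tau``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    log_J = _log_denominator(params, tau, quad_opts)
    if log_J > _LOG_HUGE:
        val = 2.0 * math.exp(-log_J)
    else:
        val = 2.0 / (1.0 + math.exp(log_J))
    return min(max(val, 0.0), 1.0)


def intensity(params: RescueParams, t: float,
              quad_opts: QuadratureOptions = DEFAULT_QUAD) -> float:
    """Establishment intensity R(t) = w(t) * mu * p_est(t)."""
    if params.mu == 0.0:
        return 0.0
    return wild_type_size(params, t) * params.mu * p_establish(params, t, quad_opts)


def expected_establishments(params: RescueParams,
                            quad_opts: QuadratureOptions = DEFAULT_QUAD) -> float:
    """Expected number of establishments Lambda = int_0^tau_end R(t) dt.

    Truncated at tau_end = log(w0)/alpha, the time for the deterministic
    wild-type decline to reach a single individual.
    """
    if params.mu == 0.0:
        return 0.0
    dq = derived_quantities(params)
    # Lambda integrals need only modest relative accuracy; the integrand is
    # itself an adaptive quadrature, so avoid requesting tolerances near its
    # own noise floor.
    tol = max(quad_opts.rel_tol, 1e-9) * 100.0
    pts = [dq.t_star] if 0.0 < dq.t_star < dq.tau_end else None
    val, err = quad(lambda t: intensity(params, t, quad_opts),
                    0.0, dq.tau_end, epsrel=tol, epsabs=1e-12,
                    limit=200, points=pts)
    if err > tol * abs(val) + 1e-9:
        raise QuadratureError(
            f"Lambda integral did not converge: value={val:g}, abserr={err:g}")
    return max(val, 0.0)


def _time_grid(params: RescueParams, horizon: float, n: int) -> np.ndarray:
    """Ascending grid on [0, horizon], geometrically densified near t_star
    where the establishment probability's curvature concentrates."""
    dq = derived_quantities(params)
    base = np.linspace(0.0, horizon, n)
    if 0.0 < dq.t_star < horizon:
        span = min(horizon - dq.t_star, dq.t_star, 10.0 / params.alpha)
        offsets = np.geomspace(span * 1e-3, span, n // 4)
        extra = np.concatenate([dq.t_star - offsets, [dq.t_star], dq.t_star + offsets])
        base = np.unique(np.concatenate([base, extra[(extra >= 0) & (extra <= horizon)]]))
    return base


def establishment_curve(params: RescueParams,
                        quad_opts: QuadratureOptions = DEFAULT_QUAD,
                        horizon: float | None = None) -> EstablishmentCurve:
    """Tabulate p_est on [0, horizon] (default horizon: tau_end)."""
    if horizon is None:
        horizon = derived_quantities(params).tau_end
    times = _time_grid(params, horizon, quad_opts.grid_size)
    vals = np.array([p_establish(params, float(t), quad_opts) for t in times])
    return EstablishmentCurve(params=params, times=times, p_est=vals)


@lru_cache(maxsize=64)
def intensity_curve(params: RescueParams,
                    quad_opts: QuadratureOptions = DEFAULT_QUAD) -> IntensityCurve:
    """Tabulate R(t) on [0, tau_end] with its cumulative integral (cached).

    The cumulative curve backs the waiting-time densities; ``Lambda_exact``
    comes from independent adaptive quadrature of R.
    """
    dq = derived_quantities(params)
    times = _time_grid(params, dq.tau_end, quad_opts.grid_size)
    R = np.array([intensity(params, float(t), quad_opts) for t in times])
    cum = np.concatenate([[0.0], cumulative_trapezoid(R, times)])
    lam = expected_establishments(params, quad_opts)
    return IntensityCurve(params=params, times=times, R=R, cum_R=cum, Lambda_exact=lam)
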