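"""Numba event loops for the birth-death simulator and the single-lineage
Monte-Carlo establishment oracle.

The population loop follows the classic exact scheme: draw the waiting time
from an exponential with rate equal to the sum of all event rates at the
current state, pick the event proportionally to its rate, update, repeat.
Per-lineage mutant rates are aggregated into total mutant birth/death rates
(density acts identically on every lineage); the lineage is chosen
proportionally to its size only once an event of that class fires, reusing
the residual of the event-selection uniform (exact: conditional on the event
class, the within-class position of the selector is itself uniform).

The single-lineage oracle instead uses Lewis-Shedler thinning, which is exact
for time-varying rates even when waiting times are long compared to the rate
of environmental change; it is the independent check on the establishment-
probability quadrature.

Randomness comes from an inline xorshift128+ generator seeded through
splitmix64 -- a deliberate choice over numba's MT19937 binding, whose
per-draw overhead dominates these tight loops.  Identical seeds reproduce
identical trajectories bit-for-bit.
"""

import numba as nb
import numpy as np

STATUS_EXTINCTION = 0
STATUS_RESCUED = 1
STATUS_EVENT_CAP = 2

_U64 = np.uint64
_DOUBLE_SCALE = 1.1102230246251565e-16  # 2^-53


@nb.njit(cache=True, inline="always")
def _seed_state(seed):
    """Expand a 64-bit seed into xorshift128+ state via splitmix64."""
    state = np.empty(2, np.uint64)
    z = _U64(seed)
    for i in range(2):
        z += _U64(0x9E3779B97F4A7C15)
        x = z
        x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
        state[i] = x ^ (x >> _U64(31))
    return state


@nb.njit(cache=True, inline="always")
def _next_double(state):
    """xorshift128+ step -> double in [0, 1)."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << _U64(23)
    s1 ^= s1 >> _U64(17)
    s1 ^= s0
    s1 ^= s0 >> _U64(26)
    state[1] = s1
    return ((s0 + s1) >> _U64(11)) * _DOUBLE_SCALE


@nb.njit(cache=True, fastmath=True)
def run_rescue(w0, K, alpha, bm, dm, dw, mu, m_stop, seed, max_events, checkpoints):
    """One replicate of the rescue birth-death process.

    Returns (status, t, w, lineage_sizes, lineage_origins, n_mutations,
    n_events, w_at_checkpoints).
    """
    rng = _seed_state(seed)
    bw = dw - alpha
    w = w0
    t = 0.0
    cap = 64
    sizes = np.zeros(cap, np.int64)
    origins = np.zeros(cap, np.float64)
    n_alive = 0
    total_m = 0
    n_mut = 0
    n_events = 0
    inv_K = 1.0 / K
    n_chk = checkpoints.shape[0]
    w_chk = np.zeros(n_chk, np.int64)
    i_chk = 0
    status = STATUS_EXTINCTION

    while True:
        if m_stop > 0.0 and total_m >= m_stop:
            status = STATUS_RESCUED
            break
        if w == 0 and total_m == 0:
            status = STATUS_EXTINCTION
            break
        if n_events >= max_events:
            status = STATUS_EVENT_CAP
            break

        dens = 1.0 - (total_m + w) * inv_K
        beff = bm * dens if dens > 0.0 else 0.0
        wf = float(w)
        mf = float(total_m)
        r_wb = bw * wf
        r_wd = dw * wf
        r_mu = mu * wf
        r_mb = beff * mf
        total = r_wb + r_wd + r_mu + r_mb + dm * mf

        t_new = t - np.log(1.0 - _next_double(rng)) / total
        if i_chk < n_chk:
            while i_chk < n_chk and checkpoints[i_chk] < t_new:
                w_chk[i_chk] = w
                i_chk += 1
        t = t_new
        n_events += 1

        u = _next_double(rng) * total
        if u < r_wb:
            w += 1
        elif u < r_wb + r_wd:
            w -= 1
        elif u < r_wb + r_wd + r_mu:
            # mutation: one wild-type individual converts into a new lineage
            w -= 1
            if n_alive == cap:
                cap *= 2
                new_sizes = np.zeros(cap, np.int64)
                new_origins = np.zeros(cap, np.float64)
                new_sizes[:n_alive] = sizes[:n_alive]
                new_origins[:n_alive] = origins[:n_alive]
                sizes = new_sizes
                origins = new_origins
            sizes[n_alive] = 1
            origins[n_alive] = t
            n_alive += 1
            total_m += 1
            n_mut += 1
        else:
            # mutant birth or death: choose the lineage by its size, reusing
            # the residual of u within the class segment as the uniform
            birth = u < r_wb + r_wd + r_mu + r_mb
            if birth:
                frac = (u - (r_wb + r_wd + r_mu)) / r_mb
            else:
                frac = (u - (r_wb + r_wd + r_mu + r_mb)) / (dm * mf)
            v = frac * mf
            acc = 0.0
            idx = n_alive - 1
            for i in range(n_alive):
                acc += sizes[i]
                if v < acc:
                    idx = i
                    break
            if birth:
                sizes[idx] += 1
                total_m += 1
            else:
                sizes[idx] -= 1
                total_m -= 1
                if sizes[idx] == 0:
                    n_alive -= 1
                    sizes[idx] = sizes[n_alive]
                    origins[idx] = origins[n_alive]

    while i_chk < n_chk:
        w_chk[i_chk] = w
        i_chk += 1
    return (status, t, w, sizes[:n_alive].copy(), origins[:n_alive].copy(),
            n_mut, n_events, w_chk)


@nb.njit(cache=True, fastmath=True)
def lineage_establishment_mc(n_lineages, tau, w0, K, alpha, bm, dm, m_est, seed):
    """Count lineages (each starting as one mutant at time tau) that reach
    size ``m_est`` before extinction, under birth rate bm*(1 - w(t)/K) and
    death rate dm.  Exact via thinning with envelope rate (bm + dm)*m.
    """
    rng = _seed_state(seed)
    n_success = 0
    for _ in range(n_lineages):
        m = 1
        t = tau
        while 0 < m < m_est:
            envelope = (bm + dm) * m
            t -= np.log(1.0 - _next_double(rng)) / envelope
            dens = 1.0 - w0 * np.exp(-alpha * t) / K
            b = bm * dens if dens > 0.0 else 0.0
            u = _next_double(rng) * envelope
            if u < (b + dm) * m:
                # real event: birth with probability b/(b + dm)
                if u < b * m:
                    m += 1
                else:
                    m -= 1
        if m >= m_est:
            n_success += 1
    return n_success
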