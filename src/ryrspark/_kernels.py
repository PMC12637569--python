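"""Numba inner loop of the exact stochastic simulation.

The direct-method SSA over all subunit flips.  Propensities are maintained
incrementally: a flip of subunit i changes only the coupling factors of its
<= 4 neighbors, and the global Ca feedback enters solely through the scalar
prefactor ``kfo*Ca`` of the factorized opening sum

    R_open = kfo*Ca * sum_{closed i} gamma_i,    R_close = kb * sum_{open i} 1/gamma_i,

so a change of the conducting-channel count is an O(1) update.  The running
sums are refreshed from scratch every 2**16 events to bound floating-point
drift.
"""

import numpy as np
from numba import njit

# status codes returned by the kernel
THRESHOLD = 0      # spark threshold reached
TIME_CENSORED = 1  # t_max reached first
ABSORBING = 2      # total rate zero, no event possible
EVENT_CAP = 3      # safety cap on event count reached
RECORD_FULL = 4    # trajectory buffer exhausted

_REFRESH_MASK = 0xFFFF


@njit(cache=True)
def _refresh_sums(state, gamma, inv_gamma):
    sc = 0.0
    so = 0.0
    for i in range(state.size):
        if state[i] < 0:
            sc += gamma[i]
        else:
            so += inv_gamma[i]
    return sc, so


@njit(cache=True)
def run_ssa(
    nbr,            # (n, 6) int64 neighbor indices, padded with -1
    coeff,          # (n, 6) float64 exponent coefficients (delta, delta*sigma*w)
    deg,            # (n,) int64 neighbor counts
    open_min,       # subunits required open for a conducting channel
    nc,             # spark threshold on conducting-channel count
    kfo, kb, c0, g, # kinetics
    t_max,
    max_events,
    gen,            # np.random.Generator
    record,         # bool: record (t, n_open) at every change of n_open
    rec_t, rec_n,   # preallocated record buffers
):
    """One SSA run from the all-closed configuration.

    Returns (t, n_events, status, n_open, n_recorded).
    """
    n = deg.size
    n_channels = n // 4
    state = np.full(n, -1, dtype=np.int8)
    expo = np.zeros(n)
    for i in range(n):
        s = 0.0
        for k in range(deg[i]):
            s -= coeff[i, k]
        expo[i] = s
    gamma = np.exp(expo)
    inv_gamma = 1.0 / gamma
    open_cnt = np.zeros(n_channels, dtype=np.int64)
    n_open = 0

    sc, so = _refresh_sums(state, gamma, inv_gamma)
    t = 0.0
    n_events = 0
    n_rec = 0
    if record:
        rec_t[0] = 0.0
        rec_n[0] = 0
        n_rec = 1

    if n_open >= nc:
        return t, n_events, THRESHOLD, n_open, n_rec

    while True:
        a = kfo * (c0 + g * n_open)
        big_r = a * sc + kb * so
        if big_r <= 0.0:
            return t, n_events, ABSORBING, n_open, n_rec
        dt = gen.exponential(1.0) / big_r
        if t + dt >= t_max:
            return t_max, n_events, TIME_CENSORED, n_open, n_rec
        t += dt

        target = gen.random() * big_r
        acc = 0.0
        chosen = -1
        for i in range(n):
            if state[i] < 0:
                r = a * gamma[i]
            else:
                r = kb * inv_gamma[i]
            acc += r
            if acc >= target:
                chosen = i
                break
        if chosen < 0:
            # float round-off overshoot: take the last subunit with positive rate
            for i in range(n - 1, -1, -1):
                r = a * gamma[i] if state[i] < 0 else kb * inv_gamma[i]
                if r > 0.0:
                    chosen = i
                    break

        i = chosen
        ch = i >> 2
        changed = False
        if state[i] < 0:
            sc -= gamma[i]
            so += inv_gamma[i]
            state[i] = 1
            open_cnt[ch] += 1
            if open_cnt[ch] == open_min:
                n_open += 1
                changed = True
        else:
            so -= inv_gamma[i]
            sc += gamma[i]
            state[i] = -1
            if open_cnt[ch] == open_min:
                n_open -= 1
                changed = True
            open_cnt[ch] -= 1

        s_new = float(state[i])
        for k in range(deg[i]):
            j = nbr[i, k]
            d = 2.0 * coeff[i, k] * s_new
            expo[j] += d
            g_new = np.exp(expo[j])
            if state[j] < 0:
                sc += g_new - gamma[j]
            else:
                so += 1.0 / g_new - inv_gamma[j]
            gamma[j] = g_new
            inv_gamma[j] = 1.0 / g_new

        n_events += 1
        if changed and record:
            if n_rec >= rec_t.size:
                return t, n_events, RECORD_FULL, n_open, n_rec
            rec_t[n_rec] = t
            rec_n[n_rec] = n_open
            n_rec += 1
        if n_open >= nc:
            return t, n_events, THRESHOLD, n_open, n_rec
        if n_events >= max_events:
            return t, n_events, EVENT_CAP, n_open, n_rec
        if n_events & _REFRESH_MASK == 0:
            sc, so = _refresh_sums(state, gamma, inv_gamma)
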