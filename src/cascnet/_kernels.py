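"""Numba step loops for the discrete-time Bernoulli simulators.

All simulators use the synchronous-update scheme: per time step of width dt,
every eligible individual draws an independent Bernoulli with the probability
computed from the state at the start of the step.  Seeding goes through
numba's internal np.random state, so runs are reproducible per (seed, config).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_STATUS_OK = 0
_STATUS_PROB_OVERFLOW = 1


@njit(cache=True)
def markov_sis(N, beta, gamma, rho, dt, n_steps, n_inf0, seed):
    """Agent-level SIS with spontaneous activation.

    Returns (times, ids, infected_count_per_step, status).  Infection (S->I)
    times are the events; recoveries are state changes only.
    """
    np.random.seed(seed)
    infected = np.zeros(N, dtype=np.uint8)
    for k in range(n_inf0):
        infected[k] = 1
    n_inf = n_inf0
    cap = 1024
    times = np.empty(cap, dtype=np.float64)
    ids = np.empty(cap, dtype=np.int64)
    n_ev = 0
    traj = np.empty(n_steps, dtype=np.int64)
    status = _STATUS_OK
    p_rec = gamma * dt
    for step in range(n_steps):
        i_frac = n_inf / N
        p_inf = (beta * i_frac + rho) * dt
        if p_inf >= 1.0 or p_rec >= 1.0:
            status = _STATUS_PROB_OVERFLOW
            break
        t = (step + 1) * dt
        d_inf = 0
        for a in range(N):
            if infected[a] == 0:
                if np.random.random() < p_inf:
                    infected[a] = 1
                    d_inf += 1
                    if n_ev == cap:
                        cap *= 2
                        new_t = np.empty(cap, dtype=np.float64)
                        new_i = np.empty(cap, dtype=np.int64)
                        new_t[:n_ev] = times
                        new_i[:n_ev] = ids
                        times = new_t
                        ids = new_i
                    times[n_ev] = t
                    ids[n_ev] = a
                    n_ev += 1
            else:
                if np.random.random() < p_rec:
                    infected[a] = 0
                    d_inf -= 1
        n_inf += d_inf
        traj[step] = n_inf
    return times[:n_ev], ids[:n_ev], traj, status


@njit(cache=True)
def hawkes_univariate(N, rho, R0, tau, refr_steps, dt, n_steps, seed):
    """Population Hawkes process with exponential kernel.

    Per-capita intensity rho + e(t) with recursive excitation
    e(t) = (R0/N) sum_k h(t - t_k), h(t) = exp(-t/tau)/tau.  With
    ``refr_steps > 0`` each firing individual is silenced for a deterministic
    refractory window of that many steps (revised model); 0 gives the
    original linear model.  Returns (times, counts_per_step, status).
    """
    np.random.seed(seed)
    decay = np.exp(-dt / tau)
    kick = R0 / (N * tau)
    e = 0.0
    n_refr = 0
    ring = np.zeros(max(refr_steps, 1), dtype=np.int64)
    cap = 1024
    times = np.empty(cap, dtype=np.float64)
    n_ev = 0
    counts = np.zeros(n_steps, dtype=np.int64)
    status = _STATUS_OK
    for step in range(n_steps):
        p = (rho + e) * dt
        if p >= 1.0:
            status = _STATUS_PROB_OVERFLOW
            break
        if refr_steps > 0:
            slot = step % refr_steps
            n_refr -= ring[slot]
            ring[slot] = 0
            n_avail = N - n_refr
        else:
            n_avail = N
        k = np.random.binomial(n_avail, p) if n_avail > 0 else 0
        if k > 0:
            t = (step + 1) * dt
            while n_ev + k > cap:
                cap *= 2
                new_t = np.empty(cap, dtype=np.float64)
                new_t[:n_ev] = times[:n_ev]
                times = new_t
            for _ in range(k):
                times[n_ev] = t
                n_ev += 1
            if refr_steps > 0:
                ring[step % refr_steps] = k
                n_refr += k
        counts[step] = k
        e = e * decay + k * kick
    return times[:n_ev], counts, status


@njit(cache=True)
def hawkes_multivariate(A, rho, tau, dt, n_steps, seed):
    """N-node mutually exciting process, exponential kernel, Bernoulli thinning.

    lambda_i(t) = rho_i + sum_j A[i, j] * s_j(t), where s_j is the summed
    kernel of node j's past events, updated recursively.  Returns
    (times, node_ids, status).
    """
    np.random.seed(seed)
    n = A.shape[0]
    decay = np.exp(-dt / tau)
    s = np.zeros(n)
    lam = np.zeros(n)
    cap = 1024
    times = np.empty(cap, dtype=np.float64)
    ids = np.empty(cap, dtype=np.int64)
    n_ev = 0
    status = _STATUS_OK
    for step in range(n_steps):
        lam = rho + A @ s
        t = (step + 1) * dt
        s *= decay
        for j in range(n):
            p = lam[j] * dt
            if p >= 1.0:
                status = _STATUS_PROB_OVERFLOW
                return times[:n_ev], ids[:n_ev], status
            if np.random.random() < p:
                if n_ev == cap:
                    cap *= 2
                    new_t = np.empty(cap, dtype=np.float64)
                    new_i = np.empty(cap, dtype=np.int64)
                    new_t[:n_ev] = times
                    new_i[:n_ev] = ids
                    times = new_t
                    ids = new_i
                times[n_ev] = t
                ids[n_ev] = j
                n_ev += 1
                s[j] += 1.0 / tau
    return times[:n_ev], ids[:n_ev], status
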