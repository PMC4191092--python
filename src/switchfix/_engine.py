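"""Numba-jitted Monte Carlo kernels for the joint (i, sigma) process.

Each run re-seeds numba's NumPy-compatible RNG with its own 32-bit seed, so
ensembles are reproducible and order-independent.  The discrete step order
matches the one-step kernel factorisation exactly: population move drawn
with the step-start environment, then the environment move.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _next_env(mu_cum_row, r):
    s2 = 0
    while mu_cum_row[s2] <= r:
        s2 += 1
    return s2


@njit(cache=True)
def discrete_trajectory(tp, tm, mu_cum, i0, s0, max_steps, seed, absorbing):
    """Single discrete-time trajectory; returns (i_series, s_series, n_steps)."""
    np.random.seed(seed)
    N = tp.shape[1] - 1
    i_series = np.empty(max_steps + 1, np.int64)
    s_series = np.empty(max_steps + 1, np.int64)
    i, s = i0, s0
    i_series[0] = i
    s_series[0] = s
    n = 0
    for step in range(max_steps):
        if absorbing and (i == 0 or i == N):
            break
        r1 = np.random.random()
        a = tp[s, i]
        if r1 < a:
            i += 1
        elif r1 < a + tm[s, i]:
            i -= 1
        s = _next_env(mu_cum[s], np.random.random())
        n = step + 1
        i_series[n] = i
        s_series[n] = s
    return i_series[:n + 1], s_series[:n + 1], n


@njit(cache=True)
def discrete_ensemble_fixation(tp, tm, mu_cum, i0, s0_arr, seeds, max_steps):
    """Run to absorption; returns (absorbed, fixed, steps) per run."""
    n_runs = seeds.shape[0]
    N = tp.shape[1] - 1
    absorbed = np.zeros(n_runs, np.bool_)
    fixed = np.zeros(n_runs, np.bool_)
    steps = np.zeros(n_runs, np.int64)
    for r in range(n_runs):
        np.random.seed(seeds[r])
        i = i0
        s = s0_arr[r]
        st = 0
        while 0 < i < N and st < max_steps:
            r1 = np.random.random()
            a = tp[s, i]
            if r1 < a:
                i += 1
            elif r1 < a + tm[s, i]:
                i -= 1
            s = _next_env(mu_cum[s], np.random.random())
            st += 1
        steps[r] = st
        absorbed[r] = i == 0 or i == N
        fixed[r] = i == N
    return absorbed, fixed, steps


@njit(cache=True)
def discrete_ensemble_histogram(tp, tm, mu_cum, i0, s0_arr, seeds,
                                n_steps, sample_every):
    """Occupancy counts over i at sampled times, plus environment counts."""
    n_runs = seeds.shape[0]
    N = tp.shape[1] - 1
    n_samples = n_steps // sample_every
    counts = np.zeros((n_samples, N + 1), np.int64)
    env_counts = np.zeros(mu_cum.shape[0], np.int64)
    for r in range(n_runs):
        np.random.seed(seeds[r])
        i = i0
        s = s0_arr[r]
        for st in range(n_steps):
            r1 = np.random.random()
            a = tp[s, i]
            if r1 < a:
                i += 1
            elif r1 < a + tm[s, i]:
                i -= 1
            s = _next_env(mu_cum[s], np.random.random())
            if (st + 1) % sample_every == 0:
                counts[(st + 1) // sample_every - 1, i] += 1
                env_counts[s] += 1
    return counts, env_counts


@njit(cache=True)
def gillespie_trajectory(tp, tm, rates, m_out, i0, s0, t_max, seed,
                         absorbing, max_events):
    """Continuous-time trajectory; returns (times, i_series, s_series, n)."""
    np.random.seed(seed)
    N = tp.shape[1] - 1
    omega = rates.shape[0]
    times = np.empty(max_events + 1, np.float64)
    i_series = np.empty(max_events + 1, np.int64)
    s_series = np.empty(max_events + 1, np.int64)
    t = 0.0
    i, s = i0, s0
    times[0] = 0.0
    i_series[0] = i
    s_series[0] = s
    n = 0
    for _ in range(max_events):
        if absorbing and (i == 0 or i == N):
            break
        total = tp[s, i] + tm[s, i] + m_out[s]
        if total <= 0.0:
            break
        t += np.random.exponential(1.0 / total)
        if t > t_max:
            break
        u = np.random.random() * total
        if u < tp[s, i]:
            i += 1
        elif u < tp[s, i] + tm[s, i]:
            i -= 1
        else:
            u -= tp[s, i] + tm[s, i]
            acc = 0.0
            for s2 in range(omega):
                if s2 == s:
                    continue
                acc += rates[s, s2]
                if u < acc:
                    s = s2
                    break
        n += 1
        times[n] = t
        i_series[n] = i
        s_series[n] = s
    return times[:n + 1], i_series[:n + 1], s_series[:n + 1], n


@njit(cache=True)
def gillespie_ensemble_fixation(tp, tm, rates, m_out, i0, s0_arr, seeds,
                                t_max, max_events):
    """Continuous-time runs to absorption; (absorbed, fixed, times) per run."""
    n_runs = seeds.shape[0]
    N = tp.shape[1] - 1
    omega = rates.shape[0]
    absorbed = np.zeros(n_runs, np.bool_)
    fixed = np.zeros(n_runs, np.bool_)
    t_abs = np.zeros(n_runs, np.float64)
    for r in range(n_runs):
        np.random.seed(seeds[r])
        i = i0
        s = s0_arr[r]
        t = 0.0
        for _ in range(max_events):
            if i == 0 or i == N:
                break
            total = tp[s, i] + tm[s, i] + m_out[s]
            t += np.random.exponential(1.0 / total)
            if t > t_max:
                break
            u = np.random.random() * total
            if u < tp[s, i]:
                i += 1
            elif u < tp[s, i] + tm[s, i]:
                i -= 1
            else:
                u -= tp[s, i] + tm[s, i]
                acc = 0.0
                for s2 in range(omega):
                    if s2 == s:
                        continue
                    acc += rates[s, s2]
                    if u < acc:
                        s = s2
                        break
        t_abs[r] = t
        absorbed[r] = i == 0 or i == N
        fixed[r] = i == N
    return absorbed, fixed, t_abs
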