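"""Fixation statistics for the continuous-time switching-environment model.

In continuous time, birth/death events (rates ``T+_{i,s}``, ``T-_{i,s}``)
and environment switches (rates ``m_{s->s'}``) are separate, competing
exponential events.  The stationary backward equations for the fixation
probability, the mean unconditional fixation time and the conditional
(on fixation) time are linear systems with the joint-process generator,
solved by sparse LU with iterative refinement.  No diffusion approximation
is used anywhere: the switching process has no continuum limit.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix

from scipy.sparse.linalg import splu

from .env_model import EnvironmentChainContinuous
from .fixation_discrete import (FixationSolution, SolverDiagnostics,
                                RESIDUAL_TOL, _MAX_REFINE)
from .game_model import BirthDeathModel

__all__ = [
    "fixation_probabilities_ct",
    "unconditional_times_ct",
    "conditional_times_ct",
    "solve_fixation_ct",
]


def _check_ct(model: BirthDeathModel, chain: EnvironmentChainContinuous):
    if model.time_convention != "continuous":
        raise ValueError("continuous-time solver requires a continuous model "
                         "(see BirthDeathModel.as_continuous)")
    if model.omega != chain.omega:
        raise ValueError(
            f"model has {model.omega} environments but chain has {chain.omega}"
        )
    if not model.absorbing:
        raise ValueError("fixation solvers require an absorbing model")
    if not np.all(np.isfinite(model.t_plus)) or not np.all(np.isfinite(model.t_minus)):
        raise ValueError("rates must be finite")


def _interior_operator(model: BirthDeathModel, chain: EnvironmentChainContinuous):
    """Backward operator A over interior states, plus inflow to fixation.

    For interior (i, s) the stationary backward equation is

        (T+ + T- + sum_s' m_{s,s'}) f_{i,s}
            = T+ f_{i+1,s} + T- f_{i-1,s} + sum_{s'!=s} m_{s,s'} f_{i,s'} + r_{i,s}

    i.e. A f = r + (inflow from boundary values); A = diag(exit) - offdiag.
    """
    N, omega = model.N, model.omega
    m = chain.rates.copy()
    np.fill_diagonal(m, 0.0)
    m_out = m.sum(axis=1)
    tp, tm = model.t_plus, model.t_minus

    exit_rate = tp[:, 1:N].T + tm[:, 1:N].T + m_out[None, :]  # (N-1, omega)
    if np.any(exit_rate <= 0):
        raise ValueError("zero total exit rate at an interior state")

    def idx(i, s):
        return (i - 1) * omega + s

    n = (N - 1) * omega
    rows, cols, data = [], [], []
    i_int = np.arange(1, N)
    for s in range(omega):
        rows.append(idx(i_int, s))
        cols.append(idx(i_int, s))
        data.append(exit_rate[:, s])
        up = i_int[i_int + 1 <= N - 1]
        rows.append(idx(up, s))
        cols.append(idx(up + 1, s))
        data.append(-tp[s, up])
        dn = i_int[i_int - 1 >= 1]
        rows.append(idx(dn, s))
        cols.append(idx(dn - 1, s))
        data.append(-tm[s, dn])
        for s2 in range(omega):
            if s2 == s or m[s, s2] == 0.0:
                continue
            rows.append(idx(i_int, s))
            cols.append(idx(i_int, s2))
            data.append(np.full(N - 1, -m[s, s2]))
    A = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    # inflow to the fixation boundary i = N from i = N-1
    fix_inflow = np.zeros(n)
    for s in range(omega):
        fix_inflow[idx(N - 1, s)] = tp[s, N - 1]
    return A, splu(A), fix_inflow


def _refined(A, lu, b):
    x = lu.solve(b)
    scale = max(1.0, np.abs(b).max())
    residual = np.inf
    for k in range(_MAX_REFINE + 1):
        r = b - A @ x
        residual = np.abs(r).max() / scale
        if residual <= RESIDUAL_TOL or k == _MAX_REFINE:
            break
        x = x + lu.solve(r)
    return x, SolverDiagnostics(residual=float(residual), refinement_steps=k,
                                method="sparse_lu_ct")


def fixation_probabilities_ct(model: BirthDeathModel,
                              chain: EnvironmentChainContinuous,
                              *, _workspace=None):
    """Fixation probabilities phi[i, s] of the continuous-time model."""
    _check_ct(model, chain)
    A, lu, fix_inflow = _workspace or _interior_operator(model, chain)
    x, diag = _refined(A, lu, fix_inflow)
    N, omega = model.N, model.omega
    phi = np.zeros((N + 1, omega))
    phi[1:N] = x.reshape(N - 1, omega)
    phi[N] = 1.0
    return phi, diag


def unconditional_times_ct(model: BirthDeathModel,
                           chain: EnvironmentChainContinuous,
                           *, _workspace=None):
    """Mean unconditional fixation times t[i, s] in model time units."""
    _check_ct(model, chain)
    A, lu, _ = _workspace or _interior_operator(model, chain)
    x, diag = _refined(A, lu, np.ones(A.shape[0]))
    N, omega = model.N, model.omega
    t = np.zeros((N + 1, omega))
    t[1:N] = x.reshape(N - 1, omega)
    return t, diag


def conditional_times_ct(model: BirthDeathModel,
                         chain: EnvironmentChainContinuous,
                         phi: Optional[np.ndarray] = None,
                         *, _workspace=None):
    """Mean fixation times conditioned on absorption at i = N."""
    _check_ct(model, chain)
    ws = _workspace or _interior_operator(model, chain)
    A, lu, _ = ws
    if phi is None:
        phi, _ = fixation_probabilities_ct(model, chain, _workspace=ws)
    N, omega = model.N, model.omega
    phi_interior = phi[1:N].ravel()
    if np.any(phi_interior <= 0):
        raise ValueError("interior fixation probability vanishes")
    x, diag = _refined(A, lu, phi_interior)
    tau = np.full((N + 1, omega), np.nan)
    tau[1:N] = x.reshape(N - 1, omega) / phi[1:N]
    tau[N] = 0.0
    return tau, diag


def solve_fixation_ct(model: BirthDeathModel,
                      chain: EnvironmentChainContinuous) -> FixationSolution:
    """phi, t and tau^A of the continuous-time model in one pass."""
    _check_ct(model, chain)
    ws = _interior_operator(model, chain)
    phi, d_phi = fixation_probabilities_ct(model, chain, _workspace=ws)
    t, d_t = unconditional_times_ct(model, chain, _workspace=ws)
    tau, d_tau = conditional_times_ct(model, chain, phi, _workspace=ws)
    return FixationSolution(
        phi=phi, t_uncond=t, t_cond=tau, N=model.N, labels=model.labels,
        diagnostics={"phi": d_phi, "t_uncond": d_t, "t_cond": d_tau},
    )
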