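"""Exact fixation statistics for the discrete-time switching-environment model.

The joint process over states ``(i, sigma)`` is a Markov chain whose one-step
kernel factorises as a birth/death move using the step-start environment
followed by an environment move,

``R_{(i,s)->(i+1,s')} = T+_{i,s} mu_{s->s'}`` (and analogously for ``i-1``
and staying put).  Fixation probabilities ``phi_{i,s}``, mean unconditional
fixation times ``t_{i,s}`` and mean conditional (on fixation at ``i = N``)
times ``tau^A_{i,s}`` satisfy first-step balance equations that are solved
here by sparse LU with iterative refinement.  The affine forward recursion
of the same equations (which requires the switching matrix to be invertible)
is retained as an independent cross-check and runs in extended precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.sparse import csr_matrix, identity
from scipy.sparse.linalg import splu

from .env_model import EnvironmentChainDiscrete, invert_chain
from .game_model import BirthDeathModel

__all__ = [
    "StepKernel",
    "FixationSolution",
    "SolverDiagnostics",
    "assemble_step_kernel",
    "fixation_probabilities",
    "unconditional_times",
    "conditional_times",
    "solve_fixation",
    "recursion_solver",
]

#: target residual (infinity norm) for the refined linear solves
RESIDUAL_TOL = 1e-10
_MAX_REFINE = 10


@dataclass(frozen=True)
class SolverDiagnostics:
    residual: float
    refinement_steps: int
    method: str = "sparse_lu"


@dataclass(frozen=True)
class StepKernel:
    """One-step transition kernel over the joint (i, sigma) state space.

    Joint states are indexed ``i * omega + s``.
    """

    matrix: csr_matrix
    N: int
    omega: int
    labels: tuple

    def index(self, i: int, s: int) -> int:
        return i * self.omega + s

    @property
    def n_states(self) -> int:
        return (self.N + 1) * self.omega


@dataclass(frozen=True)
class FixationSolution:
    """Fixation probabilities and mean times over all initial states.

    Arrays are indexed ``[i, s]`` with ``s`` the environment index.  Times
    are in elementary steps; ``*_generations`` properties divide by N
    (one generation = N birth/death steps).  ``t_cond[0, s]`` is NaN: the
    conditional time is undefined from the extinction boundary.
    """

    phi: np.ndarray
    t_uncond: np.ndarray
    t_cond: np.ndarray
    N: int
    labels: tuple
    diagnostics: Dict[str, SolverDiagnostics] = field(default_factory=dict)

    @property
    def t_uncond_generations(self) -> np.ndarray:
        return self.t_uncond / self.N

    @property
    def t_cond_generations(self) -> np.ndarray:
        return self.t_cond / self.N


def _check_dimensions(model: BirthDeathModel, chain: EnvironmentChainDiscrete):
    if model.omega != chain.omega:
        raise ValueError(
            f"model has {model.omega} environments but chain has {chain.omega}"
        )
    if model.time_convention != "discrete":
        raise ValueError("discrete solver requires a discrete-time model")


def assemble_step_kernel(model: BirthDeathModel,
                         chain: EnvironmentChainDiscrete) -> StepKernel:
    """Assemble the sparse one-step kernel of the joint (i, sigma) chain."""
    _check_dimensions(model, chain)
    N, omega = model.N, model.omega
    mu = chain.mu
    tp, tm = model.t_plus, model.t_minus
    stay = 1.0 - tp - tm

    rows, cols, data = [], [], []
    i_all = np.arange(N + 1)
    for s in range(omega):
        for s2 in range(omega):
            w = mu[s, s2]
            if w == 0.0:
                continue
            # i -> i+1
            up = i_all[:-1]
            rows.append(up * omega + s)
            cols.append((up + 1) * omega + s2)
            data.append(tp[s, up] * w)
            # i -> i-1
            dn = i_all[1:]
            rows.append(dn * omega + s)
            cols.append((dn - 1) * omega + s2)
            data.append(tm[s, dn] * w)
            # i -> i
            rows.append(i_all * omega + s)
            cols.append(i_all * omega + s2)
            data.append(stay[s, i_all] * w)
    matrix = csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=((N + 1) * omega, (N + 1) * omega),
    )
    matrix.sum_duplicates()
    return StepKernel(matrix=matrix, N=N, omega=omega, labels=model.labels)


def _interior_system(kernel: StepKernel):
    """LU factorisation of (I - R) restricted to interior states."""
    N, omega = kernel.N, kernel.omega
    interior = np.concatenate(
        [np.arange(i * omega, (i + 1) * omega) for i in range(1, N)]
    )
    fix_states = np.arange(N * omega, (N + 1) * omega)
    R = kernel.matrix
    A = (identity(interior.size, format="csr") - R[interior][:, interior]).tocsc()
    return interior, fix_states, A, splu(A)


def _refined_solve(A, lu, b):
    x = lu.solve(b)
    scale = max(1.0, np.abs(b).max()) if b.size else 1.0
    residual = np.inf
    for k in range(_MAX_REFINE + 1):
        r = b - A @ x
        residual = np.abs(r).max() / scale if r.size else 0.0
        if residual <= RESIDUAL_TOL or k == _MAX_REFINE:
            break
        x = x + lu.solve(r)
    return x, SolverDiagnostics(residual=float(residual), refinement_steps=k)


def _require_absorbing(model: BirthDeathModel):
    if not model.absorbing:
        raise ValueError("fixation solvers require an absorbing (u = 0) model")


def fixation_probabilities(model: BirthDeathModel,
                           chain: EnvironmentChainDiscrete,
                           *, _workspace=None):
    """Fixation probabilities phi[i, s], boundary rows 0 (i=0) and 1 (i=N).

    Returns ``(phi, diagnostics)``.
    """
    _require_absorbing(model)
    kernel = assemble_step_kernel(model, chain)
    interior, fix_states, A, lu = _workspace or _interior_system(kernel)
    b = np.asarray(kernel.matrix[interior][:, fix_states].sum(axis=1)).ravel()
    x, diag = _refined_solve(A, lu, b)
    N, omega = kernel.N, kernel.omega
    phi = np.zeros((N + 1, omega))
    phi[1:N] = x.reshape(N - 1, omega)
    phi[N] = 1.0
    return phi, diag


def unconditional_times(model: BirthDeathModel,
                        chain: EnvironmentChainDiscrete,
                        *, _workspace=None):
    """Mean unconditional fixation times t[i, s] in elementary steps."""
    _require_absorbing(model)
    kernel = assemble_step_kernel(model, chain)
    interior, fix_states, A, lu = _workspace or _interior_system(kernel)
    b = np.ones(interior.size)
    x, diag = _refined_solve(A, lu, b)
    N, omega = kernel.N, kernel.omega
    t = np.zeros((N + 1, omega))
    t[1:N] = x.reshape(N - 1, omega)
    return t, diag


def conditional_times(model: BirthDeathModel,
                      chain: EnvironmentChainDiscrete,
                      phi: Optional[np.ndarray] = None,
                      *, _workspace=None):
    """Mean fixation times conditioned on absorption at i = N.

    Solves for ``theta = phi * tau`` (boundary values zero) and returns
    ``tau = theta / phi`` with NaN at the extinction boundary i = 0.
    """
    _require_absorbing(model)
    kernel = assemble_step_kernel(model, chain)
    ws = _workspace or _interior_system(kernel)
    interior, fix_states, A, lu = ws
    if phi is None:
        phi, _ = fixation_probabilities(model, chain, _workspace=ws)
    N, omega = kernel.N, kernel.omega
    phi_interior = phi[1:N].ravel()
    if np.any(phi_interior <= 0):
        raise ValueError("interior fixation probability vanishes; "
                         "model violates interior positivity")
    x, diag = _refined_solve(A, lu, phi_interior)
    theta = np.zeros((N + 1, omega))
    theta[1:N] = x.reshape(N - 1, omega)
    tau = np.full((N + 1, omega), np.nan)
    tau[1:N] = theta[1:N] / phi[1:N]
    tau[N] = 0.0
    return tau, diag


def solve_fixation(model: BirthDeathModel,
                   chain: EnvironmentChainDiscrete) -> FixationSolution:
    """Solve phi, t and tau^A in one pass (shared kernel and LU factor)."""
    _require_absorbing(model)
    kernel = assemble_step_kernel(model, chain)
    ws = _interior_system(kernel)
    phi, d_phi = fixation_probabilities(model, chain, _workspace=ws)
    t, d_t = unconditional_times(model, chain, _workspace=ws)
    tau, d_tau = conditional_times(model, chain, phi, _workspace=ws)
    return FixationSolution(
        phi=phi, t_uncond=t, t_cond=tau, N=model.N, labels=model.labels,
        diagnostics={"phi": d_phi, "t_uncond": d_t, "t_cond": d_tau},
    )


# ---------------------------------------------------------------------------
# Recursion path (cross-check; requires invertible switching matrix)
# ---------------------------------------------------------------------------

def _recursion_solve_mp(model, chain, rhs, boundary_N, mu_inv, mp):
    """Propagate the affine dependence of the solution on its i=1 slice.

    The balance equation at interior i reads, with g_i = mu @ v_i and
    diagonal matrices D+- of the birth/death probabilities,

        v_i = rhs_i + D+_i g_{i+1} + D-_i g_{i-1} + (I - D+_i - D-_i) g_i,

    so g_{i+1} (hence v_{i+1} = mu^{-1} g_{i+1}) follows from (v_{i-1}, v_i).
    Writing v_i = C_i x + e_i with x the unknown v_1 propagates the affine
    pair forward; the boundary condition at i = N closes the system.

    The forward map amplifies roundoff roughly by the product of the
    per-step growth factors (the reason the formal recursion is limited to
    modest N), so the whole propagation runs in arbitrary precision.
    """
    N, omega = model.N, model.omega
    mu = mp.matrix(chain.mu.tolist())
    tp = [[mp.mpf(x) for x in row] for row in model.t_plus.tolist()]
    tm = [[mp.mpf(x) for x in row] for row in model.t_minus.tolist()]

    C_prev, e_prev = mp.zeros(omega, omega), mp.zeros(omega, 1)
    C_cur, e_cur = mp.eye(omega), mp.zeros(omega, 1)
    gC_prev, ge_prev = mu * C_prev, mu * e_prev
    gC_cur, ge_cur = mu * C_cur, mu * e_cur
    slices = [(C_prev, e_prev), (C_cur, e_cur)]
    for i in range(1, N):
        gC_next, ge_next = mp.zeros(omega, omega), mp.zeros(omega, 1)
        C_i, e_i = slices[i]
        for s in range(omega):
            dp, dm = tp[s][i], tm[s][i]
            stay = 1 - dp - dm
            for c in range(omega):
                gC_next[s, c] = (C_i[s, c] - dm * gC_prev[s, c]
                                 - stay * gC_cur[s, c]) / dp
            ge_next[s] = (e_i[s] - mp.mpf(float(rhs[i][s])) - dm * ge_prev[s]
                          - stay * ge_cur[s]) / dp
        slices.append((mu_inv * gC_next, mu_inv * ge_next))
        gC_prev, ge_prev = gC_cur, ge_cur
        gC_cur, ge_cur = gC_next, ge_next

    C_N, e_N = slices[N]
    target = mp.matrix([[mp.mpf(float(b))] for b in boundary_N]) - e_N
    x = mp.lu_solve(C_N, target)
    out = np.zeros((N + 1, omega))
    for i in range(N + 1):
        C_i, e_i = slices[i]
        v = C_i * x + e_i
        out[i] = [float(v[s]) for s in range(omega)]
    return out


def recursion_solver(model: BirthDeathModel,
                     chain: EnvironmentChainDiscrete,
                     dps: Optional[int] = None) -> FixationSolution:
    """Forward-recursion solution of the same balance equations.

    Independent of the sparse linear-solve path; requires the switching
    matrix to be invertible (raises ``SingularSwitchingError`` otherwise).
    The affine forward propagation is exponentially ill-conditioned in N,
    so it runs in arbitrary precision (default ~``60 + 2N`` decimal digits)
    and is practical only for moderate N, where it serves as a cross-check
    of the sparse direct solvers.
    """
    _require_absorbing(model)
    _check_dimensions(model, chain)
    invert_chain(chain)  # raises SingularSwitchingError when not invertible
    import mpmath

    N, omega = model.N, model.omega
    if dps is None:
        dps = 60 + 2 * N
    with mpmath.workdps(dps):
        mu_inv = mpmath.inverse(mpmath.matrix(chain.mu.tolist()))
        zeros = np.zeros((N + 1, omega))
        phi = _recursion_solve_mp(model, chain, zeros, np.ones(omega), mu_inv,
                                  mpmath)
        ones_rhs = np.zeros((N + 1, omega))
        ones_rhs[1:N] = 1.0
        t = _recursion_solve_mp(model, chain, ones_rhs, np.zeros(omega),
                                mu_inv, mpmath)
        theta = _recursion_solve_mp(model, chain, _theta_rhs(phi, N),
                                    np.zeros(omega), mu_inv, mpmath)
    tau = np.full((N + 1, omega), np.nan)
    interior = slice(1, N)
    tau[interior] = theta[interior] / phi[interior]
    tau[N] = 0.0
    diag = SolverDiagnostics(residual=np.nan, refinement_steps=0,
                             method=f"affine_recursion_mp(dps={dps})")
    return FixationSolution(phi=phi, t_uncond=t, t_cond=tau, N=N,
                            labels=model.labels,
                            diagnostics={k: diag for k in ("phi", "t_uncond", "t_cond")})


def _theta_rhs(phi: np.ndarray, N: int) -> np.ndarray:
    rhs = phi.copy()
    rhs[0] = 0.0
    rhs[N] = 0.0
    return rhs
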