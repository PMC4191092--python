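"""Independent dense-chain oracles used by the test suite.

Everything here is built directly from the transition tables with plain
dense linear algebra (fundamental matrix of the absorbing joint chain,
Doob-conditioned chains, embedded jump chains) and never calls the package
solvers, so agreement is a genuine cross-check.
"""

import numpy as np


def dense_joint_kernel(tp, tm, mu):
    """One-step kernel of the joint (i, sigma) chain, assembled by loops."""
    omega, n_states = tp.shape
    N = n_states - 1
    n = (N + 1) * omega
    R = np.zeros((n, n))
    for i in range(N + 1):
        for s in range(omega):
            row = i * omega + s
            for s2 in range(omega):
                w = mu[s, s2]
                if i < N:
                    R[row, (i + 1) * omega + s2] += tp[s, i] * w
                if i > 0:
                    R[row, (i - 1) * omega + s2] += tm[s, i] * w
                R[row, i * omega + s2] += (1 - tp[s, i] - tm[s, i]) * w
    return R


def _index_sets(N, omega):
    interior = np.array([i * omega + s for i in range(1, N) for s in range(omega)])
    fix = np.array([N * omega + s for s in range(omega)])
    return interior, fix


def fundamental_oracle(tp, tm, mu):
    """(phi, t, tau) over all (i, sigma) from the dense fundamental matrix.

    phi: hitting probabilities of the i=N class; t: expected steps to
    absorption; tau: conditional time via the Doob-conditioned chain.
    """
    omega, n_states = tp.shape
    N = n_states - 1
    R = dense_joint_kernel(tp, tm, mu)
    interior, fix = _index_sets(N, omega)
    Q = R[np.ix_(interior, interior)]
    Nf = np.linalg.inv(np.eye(interior.size) - Q)
    phi_int = Nf @ R[np.ix_(interior, fix)].sum(axis=1)
    t_int = Nf @ np.ones(interior.size)

    phi = np.zeros((N + 1, omega))
    phi[1:N] = phi_int.reshape(N - 1, omega)
    phi[N] = 1.0
    t = np.zeros((N + 1, omega))
    t[1:N] = t_int.reshape(N - 1, omega)

    # Doob transform: condition the chain on absorption at i = N
    phi_full = phi.ravel()
    keep = interior  # interior states all have phi > 0 for valid models
    Rt = R[np.ix_(keep, keep)] * phi_full[keep][None, :] / phi_full[keep][:, None]
    to_fix = R[np.ix_(keep, fix)].sum(axis=1) / phi_full[keep]
    tau_int = np.linalg.inv(np.eye(keep.size) - Rt) @ np.ones(keep.size)
    # last step into the absorbing state is counted by the conditioned chain
    # via to_fix implicitly: rows of [Rt | to_fix] are stochastic
    assert np.allclose(Rt.sum(axis=1) + to_fix, 1.0, atol=1e-10)
    tau = np.full((N + 1, omega), np.nan)
    tau[1:N] = tau_int.reshape(N - 1, omega)
    tau[N] = 0.0
    return phi, t, tau


def jump_chain_oracle(tp, tm, m_rates):
    """(phi, t, tau) for the continuous-time model via the embedded jump chain.

    Off-diagonal entries of ``m_rates`` are the environment switching rates;
    birth/death rates are ``tp``/``tm``.  Holding times are exponential with
    the total exit rate, and the conditional time uses the Doob-conditioned
    embedded chain with unchanged holding times.
    """
    omega, n_states = tp.shape
    N = n_states - 1
    m = m_rates.copy().astype(float)
    np.fill_diagonal(m, 0.0)
    m_out = m.sum(axis=1)

    interior, fix = _index_sets(N, omega)
    n = (N + 1) * omega
    jump = np.zeros((n, n))
    hold = np.zeros(n)
    for i in range(1, N):
        for s in range(omega):
            row = i * omega + s
            total = tp[s, i] + tm[s, i] + m_out[s]
            hold[row] = 1.0 / total
            jump[row, (i + 1) * omega + s] = tp[s, i] / total
            jump[row, (i - 1) * omega + s] = tm[s, i] / total
            for s2 in range(omega):
                if s2 != s:
                    jump[row, i * omega + s2] = m[s, s2] / total

    Q = jump[np.ix_(interior, interior)]
    Nf = np.linalg.inv(np.eye(interior.size) - Q)
    phi_int = Nf @ jump[np.ix_(interior, fix)].sum(axis=1)
    t_int = Nf @ hold[interior]
    phi = np.zeros((N + 1, omega))
    phi[1:N] = phi_int.reshape(N - 1, omega)
    phi[N] = 1.0
    t = np.zeros((N + 1, omega))
    t[1:N] = t_int.reshape(N - 1, omega)

    phi_full = phi.ravel()
    Rt = (jump[np.ix_(interior, interior)] * phi_full[interior][None, :]
          / phi_full[interior][:, None])
    tau_int = np.linalg.inv(np.eye(interior.size) - Rt) @ hold[interior]
    tau = np.full((N + 1, omega), np.nan)
    tau[1:N] = tau_int.reshape(N - 1, omega)
    tau[N] = 0.0
    return phi, t, tau


def single_env_closed_form(tp, tm):
    """Classical one-environment closed forms for phi and t_1, tau_1.

    ``tp``/``tm`` are (N+1,) vectors with absorbing boundaries.  Returns
    (phi, t1, tau1) computed by direct evaluation of the textbook sums.
    """
    N = len(tp) - 1
    gamma = tm[1:N] / tp[1:N]
    prods = np.concatenate([[1.0], np.cumprod(gamma)])   # prod_{j<=k}, k=0..N-1
    S = np.cumsum(prods)                                  # S_i = sum_{k=0}^{i-1} at idx i-1
    phi = np.zeros(N + 1)
    phi[1:] = S / S[-1]
    phi1 = phi[1]
    t1 = 0.0
    tau1 = 0.0
    for k in range(1, N):
        for l in range(1, k + 1):
            prod = np.prod(gamma[l:k]) if k > l else 1.0
            t1 += phi1 * prod / tp[l]
            tau1 += phi[l] * prod / tp[l]
    return phi, t1, tau1


def stationary_eigen_oracle(tp, tm, mu):
    """Stationary law of the joint mutation chain via dense eigendecomposition."""
    R = dense_joint_kernel(tp, tm, mu)
    w, v = np.linalg.eig(R.T)
    k = np.argmin(np.abs(w - 1.0))
    rho = np.real(v[:, k])
    rho = np.abs(rho)
    return rho / rho.sum()


def random_absorbing_model(rng, N, omega):
    """Random discrete absorbing transition tables with interior positivity."""
    tp = rng.uniform(0.05, 0.45, size=(omega, N + 1))
    tm = rng.uniform(0.05, 0.45, size=(omega, N + 1))
    tp[:, 0] = tp[:, N] = 0.0
    tm[:, 0] = tm[:, N] = 0.0
    return tp, tm


def random_stochastic_matrix(rng, omega):
    return rng.dirichlet(np.ones(omega), size=omega)
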