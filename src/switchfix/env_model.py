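"""Markov models of the environmental state.

The environment is a finite-state Markov process that evolves independently
of the population.  Two time conventions are supported:

* discrete time — an :math:`\\Omega\\times\\Omega` stochastic matrix
  :math:`\\mu_{\\sigma\\to\\sigma'}` of per-step switching probabilities;
* continuous time — a matrix of switching rates
  :math:`m_{\\sigma\\to\\sigma'}` (per unit time, off-diagonal).

For two environments the canonical labels are ``+1`` (first row/column) and
``-1`` (second), and the off-diagonal entries are the telegraph-process
switching probabilities :math:`p_+` and :math:`p_-`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ChainValidationError",
    "SingularSwitchingError",
    "ReducibleChainError",
    "EnvironmentChainDiscrete",
    "EnvironmentChainContinuous",
    "validate_discrete_chain",
    "validate_continuous_chain",
    "two_env_chain",
    "invert_chain",
    "stationary_occupancy",
]

#: absolute tolerance on row-stochasticity of the switching matrix
STOCHASTIC_ATOL = 1e-12

#: condition-number threshold beyond which the switching matrix is treated
#: as numerically singular (relevant for the recursion solver only)
SINGULAR_COND_THRESHOLD = 1e12


class ChainValidationError(ValueError):
    """Raised when a switching matrix fails validation."""


class SingularSwitchingError(np.linalg.LinAlgError):
    """Raised when the switching matrix is (numerically) singular.

    The recursion solver requires the inverse of the switching matrix; for a
    two-environment chain the matrix is singular exactly when
    ``p_plus + p_minus == 1``.  The direct (sparse linear-solve) path does not
    need the inverse and should be used instead.
    """


class ReducibleChainError(ValueError):
    """Raised when the environment chain is not irreducible."""


def _default_labels(omega: int) -> tuple:
    if omega == 2:
        return (+1, -1)
    return tuple(range(omega))


@dataclass(frozen=True)
class EnvironmentChainDiscrete:
    """Discrete-time environment chain with per-step switching matrix ``mu``.

    Use :func:`validate_discrete_chain` or :func:`two_env_chain` to construct
    validated instances.
    """

    mu: np.ndarray
    labels: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if self.labels is None:
            object.__setattr__(self, "labels", _default_labels(mu.shape[0]))

    @property
    def omega(self) -> int:
        return self.mu.shape[0]

    # --- two-environment (telegraph) conveniences -------------------------
    def _require_two(self):
        if self.omega != 2:
            raise ValueError("p_plus/p_minus are defined for omega == 2 only")

    @property
    def p_plus(self) -> float:
        """Probability of leaving the first (sigma = +1) environment."""
        self._require_two()
        return float(self.mu[0, 1])

    @property
    def p_minus(self) -> float:
        """Probability of leaving the second (sigma = -1) environment."""
        self._require_two()
        return float(self.mu[1, 0])

    @property
    def delta(self) -> float:
        """Determinant ``1 - p_plus - p_minus`` of the two-state matrix.

        The matrix inverse used by the recursion solver exists iff this is
        nonzero.
        """
        self._require_two()
        return 1.0 - self.p_plus - self.p_minus

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown environment label {label!r}") from None


@dataclass(frozen=True)
class EnvironmentChainContinuous:
    """Continuous-time environment chain with switching rates ``rates``.

    ``rates[s, s2]`` is the rate of a sigma -> sigma' transition for
    ``s2 != s``; the diagonal is ignored.  The generator used internally has
    diagonal ``-sum`` of the off-diagonal row entries (standard rate-matrix
    convention).
    """

    rates: np.ndarray
    labels: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if self.labels is None:
            object.__setattr__(self, "labels", _default_labels(rates.shape[0]))

    @property
    def omega(self) -> int:
        return self.rates.shape[0]

    def generator(self) -> np.ndarray:
        """Rate generator with diagonal -sum(off-diagonal)."""
        q = np.array(self.rates, dtype=float)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def exit_rates(self) -> np.ndarray:
        """Total switching rate out of each environment state."""
        q = np.array(self.rates, dtype=float)
        np.fill_diagonal(q, 0.0)
        return q.sum(axis=1)

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown environment label {label!r}") from None


def validate_discrete_chain(mu_matrix, labels=None) -> EnvironmentChainDiscrete:
    """Validate a per-step switching matrix and wrap it in a chain object.

    Raises
    ------
    ChainValidationError
        If the matrix is not square, has entries outside ``[0, 1]``, or any
        row fails to sum to one within ``STOCHASTIC_ATOL`` (the error names
        the offending row).
    """
    mu = np.asarray(mu_matrix, dtype=float)
    if mu.ndim != 2 or mu.shape[0] != mu.shape[1]:
        raise ChainValidationError(f"switching matrix must be square, got shape {mu.shape}")
    if mu.shape[0] < 1:
        raise ChainValidationError("need at least one environment state")
    if np.any(mu < 0) or np.any(mu > 1):
        bad = np.argwhere((mu < 0) | (mu > 1))[0]
        raise ChainValidationError(
            f"entry mu[{bad[0]},{bad[1]}] = {mu[tuple(bad)]} outside [0, 1]"
        )
    row_sums = mu.sum(axis=1)
    bad_rows = np.where(np.abs(row_sums - 1.0) > STOCHASTIC_ATOL)[0]
    if bad_rows.size:
        r = int(bad_rows[0])
        raise ChainValidationError(
            f"row {r} of switching matrix sums to {row_sums[r]:.12g}, expected 1"
        )
    if labels is not None and len(labels) != mu.shape[0]:
        raise ChainValidationError("labels length does not match matrix size")
    return EnvironmentChainDiscrete(mu=mu, labels=tuple(labels) if labels else None)


def validate_continuous_chain(rates, labels=None) -> EnvironmentChainContinuous:
    """Validate a matrix of switching rates (off-diagonal, non-negative)."""
    m = np.asarray(rates, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ChainValidationError(f"rate matrix must be square, got shape {m.shape}")
    off = m.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        bad = np.argwhere(off < 0)[0]
        raise ChainValidationError(
            f"rate m[{bad[0]},{bad[1]}] = {off[tuple(bad)]} is negative"
        )
    if m.shape[0] > 1 and not np.any(off > 0):
        raise ChainValidationError(
            "all switching rates are zero; use a single-environment model instead"
        )
    return EnvironmentChainContinuous(rates=m, labels=tuple(labels) if labels else None)


def two_env_chain(p_plus: float, p_minus: float) -> EnvironmentChainDiscrete:
    """Two-environment telegraph chain.

    Row order is (+1, -1): the matrix is
    ``[[1 - p_plus, p_plus], [p_minus, 1 - p_minus]]`` where ``p_sigma`` is
    the per-step probability of switching *out of* environment ``sigma``.
    """
    for name, p in (("p_plus", p_plus), ("p_minus", p_minus)):
        if not 0.0 <= p <= 1.0:
            raise ChainValidationError(f"{name} = {p} outside [0, 1]")
    mu = np.array([[1.0 - p_plus, p_plus], [p_minus, 1.0 - p_minus]])
    return EnvironmentChainDiscrete(mu=mu, labels=(+1, -1))


def invert_chain(chain: EnvironmentChainDiscrete) -> np.ndarray:
    """Matrix inverse of the switching matrix (recursion-solver path only).

    Raises :class:`SingularSwitchingError` when the matrix is numerically
    singular (relative condition number above ``SINGULAR_COND_THRESHOLD``);
    for two environments this happens exactly at ``p_plus + p_minus == 1``.
    The direct solvers do not require this inverse.
    """
    mu = chain.mu
    cond = np.linalg.cond(mu)
    if not np.isfinite(cond) or cond > SINGULAR_COND_THRESHOLD:
        raise SingularSwitchingError(
            "switching matrix is numerically singular "
            f"(cond={cond:.3g}); use the direct solver, which does not "
            "require inversion"
        )
    return np.linalg.inv(mu)


def _support_graph(matrix: np.ndarray) -> csr_matrix:
    off = matrix.copy()
    np.fill_diagonal(off, 0.0)
    return csr_matrix((off > 0).astype(np.int8))


def stationary_occupancy(chain) -> np.ndarray:
    """Stationary occupancy of the environment states.

    Left eigenvector of ``mu`` at eigenvalue 1 (discrete) or the null vector
    of the rate generator (continuous), normalised to sum to one.  For the
    two-state telegraph chain this is ``(p_minus, p_plus) / (p_plus +
    p_minus)``.

    Raises :class:`ReducibleChainError` if the chain is not irreducible
    (e.g. frozen environments), naming an absorbing subset.
    """
    if isinstance(chain, EnvironmentChainDiscrete):
        a = chain.mu.T - np.eye(chain.omega)
    elif isinstance(chain, EnvironmentChainContinuous):
        a = chain.generator().T
    else:
        raise TypeError("expected a discrete or continuous environment chain")

    omega = chain.omega
    if omega == 1:
        return np.array([1.0])

    support = chain.mu if isinstance(chain, EnvironmentChainDiscrete) else chain.rates
    n_comp, comp = connected_components(
        _support_graph(np.asarray(support, dtype=float)), connection="strong"
    )
    if n_comp > 1:
        # report one closed (absorbing) communicating class
        off = np.asarray(support, dtype=float).copy()
        np.fill_diagonal(off, 0.0)
        for c in range(n_comp):
            members = np.where(comp == c)[0]
            outside = np.setdiff1d(np.arange(omega), members)
            if outside.size == 0 or not np.any(off[np.ix_(members, outside)] > 0):
                names = [chain.labels[m] for m in members]
                raise ReducibleChainError(
                    f"environment chain is reducible; absorbing subset {names}"
                )
        raise ReducibleChainError("environment chain is reducible")

    # solve a^T rho = 0 with the normalisation sum(rho) = 1 appended
    system = np.vstack([a, np.ones(omega)])
    rhs = np.zeros(omega + 1)
    rhs[-1] = 1.0
    rho, *_ = np.linalg.lstsq(system, rhs, rcond=None)
    rho = np.clip(rho, 0.0, None)
    return rho / rho.sum()
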