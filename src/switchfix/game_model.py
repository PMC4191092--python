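"""Evolutionary 2x2 games and the frequency-dependent Moran process.

Per-environment payoff matrices are mapped to birth/death transition
probabilities of the Moran process with an exponential payoff-to-fitness
mapping ``f = exp(beta * pi)``.  The canonical switching game uses
``a_sigma = d_sigma = 1``, ``b_sigma = 1 + sigma*b``, ``c_sigma = 1 +
sigma*c`` with amplitudes ``b, c > 0``, so that sigma = +1 is a coexistence
game and sigma = -1 a coordination game, and both share the same interior
selection-balance point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Tuple

import numpy as np

__all__ = [
    "GameSpec",
    "BirthDeathModel",
    "expected_payoffs",
    "fitness",
    "moran_transitions",
    "moran_transitions_with_mutation",
    "birth_death_model",
    "gradient_of_selection",
    "selection_balance_point",
    "BalancePoint",
]


@dataclass(frozen=True)
class GameSpec:
    """A per-environment 2x2 game plus Moran-process parameters.

    ``payoffs[s]`` is the row ``(a, b, c, d)`` for environment index ``s``:
    a type-A individual receives ``a`` against A and ``b`` against B; a
    type-B individual receives ``c`` against A and ``d`` against B.
    """

    payoffs: np.ndarray            # (omega, 4) rows (a, b, c, d)
    beta: float                    # selection intensity, >= 0
    u: float = 0.0                 # mutation probability per birth event
    N: int = 2                     # population size
    labels: tuple = field(default=None)  # type: ignore[assignment]
    amplitudes: Optional[Tuple[float, float]] = None  # (b, c) if switching game

    def __post_init__(self):
        payoffs = np.atleast_2d(np.asarray(self.payoffs, dtype=float))
        if payoffs.shape[1] != 4:
            raise ValueError("payoffs must have rows (a, b, c, d)")
        object.__setattr__(self, "payoffs", payoffs)
        if self.labels is None:
            labels = (+1, -1) if payoffs.shape[0] == 2 else tuple(range(payoffs.shape[0]))
            object.__setattr__(self, "labels", labels)
        if self.beta < 0:
            raise ValueError("selection intensity beta must be >= 0")
        if not 0.0 <= self.u < 1.0:
            raise ValueError("mutation probability u must lie in [0, 1)")
        if self.N < 2:
            raise ValueError("population size N must be >= 2")

    @property
    def omega(self) -> int:
        return self.payoffs.shape[0]

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown environment label {label!r}") from None

    @classmethod
    def switching_game(cls, b: float, c: float, beta: float, N: int,
                       u: float = 0.0) -> "GameSpec":
        """Coexistence/coordination switching game with amplitudes (b, c)."""
        payoffs = np.array(
            [[1.0, 1.0 + b, 1.0 + c, 1.0],      # sigma = +1 (coexistence for b,c>0)
             [1.0, 1.0 - b, 1.0 - c, 1.0]]      # sigma = -1 (coordination for b,c>0)
        )
        return cls(payoffs=payoffs, beta=beta, u=u, N=N, labels=(+1, -1),
                   amplitudes=(b, c))


@dataclass(frozen=True)
class BirthDeathModel:
    """Per-environment one-step birth/death transition tables.

    ``t_plus[s, i]`` and ``t_minus[s, i]`` are the probabilities (discrete
    time) or rates (continuous time) of ``i -> i+1`` and ``i -> i-1`` in
    environment index ``s``.
    """

    N: int
    t_plus: np.ndarray             # (omega, N+1)
    t_minus: np.ndarray            # (omega, N+1)
    absorbing: bool = True
    time_convention: str = "discrete"
    labels: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        tp = np.atleast_2d(np.asarray(self.t_plus, dtype=float))
        tm = np.atleast_2d(np.asarray(self.t_minus, dtype=float))
        object.__setattr__(self, "t_plus", tp)
        object.__setattr__(self, "t_minus", tm)
        if self.labels is None:
            labels = (+1, -1) if tp.shape[0] == 2 else tuple(range(tp.shape[0]))
            object.__setattr__(self, "labels", labels)
        if tp.shape != tm.shape or tp.shape[1] != self.N + 1:
            raise ValueError("transition tables must both have shape (omega, N+1)")
        if self.time_convention not in ("discrete", "continuous"):
            raise ValueError("time_convention must be 'discrete' or 'continuous'")
        if np.any(tp < 0) or np.any(tm < 0):
            raise ValueError("transition probabilities/rates must be non-negative")
        if self.time_convention == "discrete" and np.any(tp + tm > 1 + 1e-12):
            raise ValueError("discrete model requires T+ + T- <= 1 at every state")
        if self.absorbing:
            if np.any(tp[:, [0, -1]] != 0) or np.any(tm[:, [0, -1]] != 0):
                raise ValueError("absorbing model requires zero boundary transitions")
            interior = slice(1, self.N)
            if np.any(tp[:, interior] <= 0) or np.any(tm[:, interior] <= 0):
                raise ValueError(
                    "absorbing model requires strictly positive interior T+-"
                )

    @property
    def omega(self) -> int:
        return self.t_plus.shape[0]

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown environment label {label!r}") from None

    def as_continuous(self) -> "BirthDeathModel":
        """Reinterpret the discrete per-step probabilities as rates."""
        return BirthDeathModel(N=self.N, t_plus=self.t_plus, t_minus=self.t_minus,
                               absorbing=self.absorbing,
                               time_convention="continuous", labels=self.labels)


def expected_payoffs(i: int, spec: GameSpec, sigma) -> Tuple[float, float]:
    """Expected payoffs (pi_A, pi_B) at mutant count ``i`` in environment sigma.

    Self-interaction is excluded: each individual plays the other ``N - 1``.
    ``pi_A`` is meaningful for ``i >= 1`` and ``pi_B`` for ``i <= N-1``.
    """
    N = spec.N
    if not 0 <= i <= N:
        raise ValueError(f"mutant count i={i} outside [0, {N}]")
    a, b, c, d = spec.payoffs[spec.index_of(sigma)]
    pi_a = (a * (i - 1) + b * (N - i)) / (N - 1)
    pi_b = (c * i + d * (N - i - 1)) / (N - 1)
    return float(pi_a), float(pi_b)


def fitness(payoff: float, beta: float) -> float:
    """Exponential payoff-to-fitness mapping ``exp(beta * payoff)``."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return float(np.exp(beta * payoff))


def _payoff_vectors(spec: GameSpec, s: int):
    N = spec.N
    i = np.arange(N + 1, dtype=float)
    a, b, c, d = spec.payoffs[s]
    pi_a = (a * (i - 1) + b * (N - i)) / (N - 1)
    pi_b = (c * i + d * (N - i - 1)) / (N - 1)
    return i, pi_a, pi_b


def moran_transitions(spec: GameSpec, sigma) -> Tuple[np.ndarray, np.ndarray]:
    """Mutation-free Moran transition probabilities (T+_i, T-_i) for i=0..N.

    T+_i = [i f_A / (i f_A + (N-i) f_B)] (N-i)/N and symmetrically for T-.
    Boundaries i=0 and i=N are absorbing (both entries zero).
    """
    if spec.u != 0:
        raise ValueError("moran_transitions is the u=0 case; "
                         "use moran_transitions_with_mutation")
    s = spec.index_of(sigma)
    N = spec.N
    i, pi_a, pi_b = _payoff_vectors(spec, s)
    fa = np.exp(spec.beta * pi_a)
    fb = np.exp(spec.beta * pi_b)
    denom = i * fa + (N - i) * fb
    tp = (i * fa / denom) * (N - i) / N
    tm = ((N - i) * fb / denom) * i / N
    tp[[0, N]] = 0.0
    tm[[0, N]] = 0.0
    return tp, tm


def moran_transitions_with_mutation(spec: GameSpec, sigma) -> Tuple[np.ndarray, np.ndarray]:
    """Moran transitions with birth-step mutation ``u`` in (0, 1).

    The offspring inherits the parental type with probability ``1 - u`` and
    the other type with probability ``u``, so the escape probability from
    either monomorphic state is exactly ``u``; the boundaries are no longer
    absorbing.
    """
    if not 0 < spec.u < 1:
        raise ValueError("moran_transitions_with_mutation requires u in (0, 1)")
    s = spec.index_of(sigma)
    N, u = spec.N, spec.u
    i, pi_a, pi_b = _payoff_vectors(spec, s)
    fa = np.exp(spec.beta * pi_a)
    fb = np.exp(spec.beta * pi_b)
    denom = i * fa + (N - i) * fb
    tp = (N - i) / N * ((1 - u) * i * fa + u * (N - i) * fb) / denom
    tm = i / N * ((1 - u) * (N - i) * fb + u * i * fa) / denom
    return tp, tm


def birth_death_model(spec: GameSpec, time_convention: str = "discrete") -> BirthDeathModel:
    """Assemble the full per-environment transition tables for ``spec``."""
    make = moran_transitions if spec.u == 0 else moran_transitions_with_mutation
    rows = [make(spec, lab) for lab in spec.labels]
    tp = np.vstack([r[0] for r in rows])
    tm = np.vstack([r[1] for r in rows])
    return BirthDeathModel(N=spec.N, t_plus=tp, t_minus=tm,
                           absorbing=(spec.u == 0),
                           time_convention=time_convention, labels=spec.labels)


def gradient_of_selection(model: BirthDeathModel, sigma) -> np.ndarray:
    """Net drift ``T+_i - T-_i`` of the mutant count in environment sigma."""
    s = model.index_of(sigma)
    return model.t_plus[s] - model.t_minus[s]


class BalancePoint(NamedTuple):
    i_star_real: float
    i_star_int: int
    leading_order_fraction: float


def selection_balance_point(spec: GameSpec, sigma) -> BalancePoint:
    """Interior state where the expected payoffs of A and B are equal.

    Solves ``pi_A(i) = pi_B(i)`` for real ``i`` and reports the nearest
    integer state (ties at .5 round toward N/2).  Also reports the
    leading-order fraction ``i*/N``, which for the switching-game
    parametrization equals ``b / (b + c)``.

    Raises ``ValueError`` for dominance games (no interior sign change of
    the payoff difference).
    """
    s = spec.index_of(sigma)
    N = spec.N
    a, b, c, d = spec.payoffs[s]
    # (N-1) (pi_A - pi_B) = (a - b - c + d) i + (bN - dN - a + d): linear in i
    slope = a - b - c + d
    intercept = b * N - d * N - a + d
    interior = np.arange(1, N)
    diff = slope * interior + intercept
    signs = np.sign(diff)
    nz = signs[signs != 0]
    if slope == 0 or nz.size == 0 or np.all(nz == nz[0]):
        raise ValueError(
            "no interior selection-balance point: one type dominates "
            f"in environment {sigma!r}"
        )
    i_star = -intercept / slope
    frac, floor = np.modf(i_star)
    if abs(frac - 0.5) < 1e-12:
        # tie: round toward the centre of the state space
        i_int = int(floor) + (1 if floor + 0.5 < N / 2 else 0)
    else:
        i_int = int(round(i_star))
    leading = (d - b) / slope  # limit of i*/N for large N
    return BalancePoint(float(i_star), i_int, float(leading))
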