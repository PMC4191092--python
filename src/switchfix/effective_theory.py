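"""Fast-switching effective theory and single-environment closed forms.

When environment switches are much faster than fixation, the population is
governed by occupancy-weighted *effective* transition probabilities.  For
the two-state telegraph environment the asymptotic occupancies are
``p_minus/(p_plus + p_minus)`` in sigma = +1 and ``p_plus/(p_plus +
p_minus)`` in sigma = -1, so

    T+-_{i,eff} = (p_minus T+-_{i,+1} + p_plus T+-_{i,-1}) / (p_plus + p_minus).

The resulting one-environment birth/death chain has classical closed-form
fixation probabilities and mean times, evaluated here in a numerically safe
way (log-space products for extreme gamma ratios).  These formulas are exact
for the effective chain; the approximation lies entirely in replacing the
switching model by it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import logsumexp

from .game_model import BirthDeathModel

__all__ = [
    "EffectiveModel",
    "effective_rates",
    "effective_rates_general",
    "closed_form_fixation",
    "closed_form_times",
]


@dataclass(frozen=True)
class EffectiveModel:
    """Occupancy-averaged one-environment birth/death chain."""

    N: int
    t_plus_eff: np.ndarray        # (N+1,)
    t_minus_eff: np.ndarray       # (N+1,)
    absorbing: bool = True
    weights: Tuple[float, ...] = ()

    @property
    def gamma(self) -> np.ndarray:
        """Death/birth ratio gamma_i = T-_{i,eff} / T+_{i,eff} on the interior."""
        interior = slice(1, self.N)
        tp = self.t_plus_eff[interior]
        if np.any(tp <= 0):
            raise ValueError("effective birth probability vanishes on the interior")
        return self.t_minus_eff[interior] / tp

    def as_birth_death_model(self, time_convention: str = "discrete") -> BirthDeathModel:
        """Wrap as a one-environment BirthDeathModel (for exact cross-checks)."""
        return BirthDeathModel(
            N=self.N, t_plus=self.t_plus_eff[None, :],
            t_minus=self.t_minus_eff[None, :], absorbing=self.absorbing,
            time_convention=time_convention, labels=("eff",),
        )


def effective_rates(model: BirthDeathModel, p_plus: float,
                    p_minus: float) -> EffectiveModel:
    """Effective transition probabilities for the two-environment model.

    Weights are the telegraph-process occupancies ``(p_minus, p_plus) /
    (p_plus + p_minus)`` on environments (+1, -1); raises if both switching
    probabilities are zero (no mixing).
    """
    if model.omega != 2:
        raise ValueError("effective_rates is defined for omega == 2; "
                         "see effective_rates_general for the extension")
    if p_plus < 0 or p_minus < 0 or p_plus + p_minus <= 0:
        raise ValueError("need p_plus, p_minus >= 0 with p_plus + p_minus > 0")
    w = np.array([p_minus, p_plus]) / (p_plus + p_minus)
    return _weighted(model, w)


def effective_rates_general(model: BirthDeathModel,
                            weights: np.ndarray) -> EffectiveModel:
    """Occupancy-weighted effective chain for any number of environments.

    Extension beyond the two-state telegraph case: pass the stationary
    occupancy of the environment chain as ``weights``.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (model.omega,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
        raise ValueError("weights must be a distribution over the environments")
    return _weighted(model, w)


def _weighted(model: BirthDeathModel, w: np.ndarray) -> EffectiveModel:
    return EffectiveModel(
        N=model.N,
        t_plus_eff=w @ model.t_plus,
        t_minus_eff=w @ model.t_minus,
        absorbing=model.absorbing,
        weights=tuple(w),
    )


def _log_gamma_cumulative(eff: EffectiveModel) -> np.ndarray:
    """log prod_{j=1}^{k} gamma_j for k = 1..N-1."""
    return np.cumsum(np.log(eff.gamma))


def closed_form_fixation(eff: EffectiveModel) -> np.ndarray:
    """Classical birth/death fixation probabilities on the effective chain.

    phi_i = (1 + sum_{k=1}^{i-1} prod_{j<=k} gamma_j)
          / (1 + sum_{k=1}^{N-1} prod_{j<=k} gamma_j),
    computed in log space to survive strongly biased chains.
    """
    if not eff.absorbing:
        raise ValueError("closed-form fixation requires absorbing boundaries")
    N = eff.N
    lg = _log_gamma_cumulative(eff)
    # log S_i with S_i = 1 + sum_{k=1}^{i-1} prod gamma; S_1 = 1
    terms = np.concatenate([[0.0], lg])          # log of {1, prod_1, ..., prod_{N-1}}
    log_s = np.array([logsumexp(terms[:i]) for i in range(1, N + 1)])
    phi = np.zeros(N + 1)
    phi[1:] = np.exp(log_s - log_s[-1])
    return phi


def closed_form_times(eff: EffectiveModel) -> Tuple[np.ndarray, np.ndarray]:
    """Mean unconditional and conditional fixation times on the effective chain.

    Evaluates the classical nested-sum formulas by forward recursion on the
    step differences: with d_i = t_{i+1} - t_i the interior balance gives
    ``d_i = gamma_i d_{i-1} - r_i / T+_i`` (r = 1 for the unconditional
    time, r = phi for theta = phi * tau), and the absorbing boundaries close
    the affine system in d_0.  Times are in elementary steps (divide by N
    for generations).
    """
    if not eff.absorbing:
        raise ValueError("closed-form times require absorbing boundaries")
    N = eff.N
    gamma = eff.gamma
    tp = eff.t_plus_eff[1:N]
    phi = closed_form_fixation(eff)

    def solve(rhs_interior: np.ndarray) -> np.ndarray:
        # d_i = a_i d_0 + b_i, i = 0..N-1; closure sum_i d_i = 0
        a = np.empty(N)
        b = np.empty(N)
        a[0], b[0] = 1.0, 0.0
        for i in range(1, N):
            a[i] = gamma[i - 1] * a[i - 1]
            b[i] = gamma[i - 1] * b[i - 1] - rhs_interior[i - 1] / tp[i - 1]
        d0 = -b.sum() / a.sum()
        d = a * d0 + b
        out = np.zeros(N + 1)
        out[1:] = np.cumsum(d)
        out[N] = 0.0  # exact boundary; cumsum closes to 0 up to roundoff
        return out

    t_uncond = solve(np.ones(N - 1))
    theta = solve(phi[1:N])
    t_cond = np.full(N + 1, np.nan)
    t_cond[1:N] = theta[1:N] / phi[1:N]
    t_cond[N] = 0.0
    return t_uncond, t_cond
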