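"""Seeded Monte Carlo simulation of the joint (population, environment) process.

Wraps the jitted kernels in :mod:`switchfix._engine` with trajectory and
ensemble-estimator containers.  Per-run seeds are derived from the master
seed with :class:`numpy.random.SeedSequence`, so identical (seed, config)
pairs reproduce bit-identical output and ensembles are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from . import _engine
from .env_model import (EnvironmentChainContinuous, EnvironmentChainDiscrete,
                        stationary_occupancy)
from .game_model import BirthDeathModel

__all__ = [
    "Trajectory",
    "EnsembleEstimate",
    "run_discrete",
    "run_gillespie",
    "estimate_fixation",
    "estimate_fixation_ct",
    "ensemble_distribution",
]

SigmaPolicy = Union[int, str]


@dataclass(frozen=True)
class Trajectory:
    """A single realisation of the joint process."""

    times: np.ndarray          # step index (discrete) or model time (continuous)
    i: np.ndarray
    sigma: np.ndarray          # environment labels
    absorbed: bool
    absorbing_state: Optional[int]   # 0, N, or None
    absorption_time: Optional[float]
    seed: int


@dataclass(frozen=True)
class EnsembleEstimate:
    """Ensemble estimators for fixation statistics with standard errors."""

    phi_hat: float
    phi_se: float
    t_hat: float               # mean unconditional absorption time
    t_se: float
    tau_hat: float             # mean time of runs that fixed (conditional)
    tau_se: float
    n_runs: int
    n_fixed: int
    n_unabsorbed: int
    seed: int


def _mu_cum(chain: EnvironmentChainDiscrete) -> np.ndarray:
    cum = np.cumsum(chain.mu, axis=1)
    cum[:, -1] = 1.0 + 1e-12  # guard the final bin against roundoff
    return cum


def _resolve_sigma0(policy: SigmaPolicy, labels, chain, rng) -> int:
    if isinstance(policy, str):
        if policy != "stationary":
            raise ValueError(f"unknown sigma0 policy {policy!r}")
        occ = stationary_occupancy(chain)
        return int(rng.choice(len(labels), p=occ))
    return labels.index(policy) if policy in labels else int(policy)


def _run_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)


def run_discrete(model: BirthDeathModel, chain: EnvironmentChainDiscrete,
                 i0: int, sigma0, seed: int,
                 max_steps: int = 10_000_000) -> Trajectory:
    """Simulate one discrete-time trajectory.

    Stops at absorption for absorbing (u = 0) models; hitting ``max_steps``
    without absorption is flagged via ``absorbed=False``, not an error.
    """
    if not 0 <= i0 <= model.N:
        raise ValueError("i0 outside [0, N]")
    s0 = model.index_of(sigma0)
    run_seed = int(_run_seeds(seed, 1)[0])
    i_series, s_series, n = _engine.discrete_trajectory(
        model.t_plus, model.t_minus, _mu_cum(chain), int(i0), s0,
        int(max_steps), run_seed, model.absorbing,
    )
    labels = np.asarray(model.labels)[s_series]
    absorbed = model.absorbing and (i_series[-1] == 0 or i_series[-1] == model.N)
    return Trajectory(
        times=np.arange(n + 1, dtype=float), i=i_series, sigma=labels,
        absorbed=bool(absorbed),
        absorbing_state=int(i_series[-1]) if absorbed else None,
        absorption_time=float(n) if absorbed else None, seed=seed,
    )


def run_gillespie(model: BirthDeathModel, chain: EnvironmentChainContinuous,
                  i0: int, sigma0, seed: int, t_max: float,
                  max_events: int = 10_000_000) -> Trajectory:
    """Simulate one continuous-time trajectory with exponential waiting times."""
    if model.time_convention != "continuous":
        raise ValueError("run_gillespie requires a continuous-time model")
    if not 0 <= i0 <= model.N:
        raise ValueError("i0 outside [0, N]")
    s0 = model.index_of(sigma0)
    run_seed = int(_run_seeds(seed, 1)[0])
    rates = chain.rates.copy()
    np.fill_diagonal(rates, 0.0)
    times, i_series, s_series, n = _engine.gillespie_trajectory(
        model.t_plus, model.t_minus, rates, rates.sum(axis=1),
        int(i0), s0, float(t_max), run_seed, model.absorbing, int(max_events),
    )
    labels = np.asarray(model.labels)[s_series]
    absorbed = model.absorbing and (i_series[-1] == 0 or i_series[-1] == model.N)
    return Trajectory(
        times=times, i=i_series, sigma=labels, absorbed=bool(absorbed),
        absorbing_state=int(i_series[-1]) if absorbed else None,
        absorption_time=float(times[-1]) if absorbed else None, seed=seed,
    )


def _sigma0_array(sigma0: SigmaPolicy, model, chain, seed, n_runs) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if isinstance(sigma0, str):
        if sigma0 != "stationary":
            raise ValueError(f"unknown sigma0 policy {sigma0!r}")
        occ = stationary_occupancy(chain)
        return rng.choice(model.omega, size=n_runs, p=occ).astype(np.int64)
    return np.full(n_runs, model.index_of(sigma0), dtype=np.int64)


def _summarise(absorbed, fixed, times, n_runs, seed) -> EnsembleEstimate:
    phi_hat = fixed.mean()
    phi_se = float(np.sqrt(phi_hat * (1 - phi_hat) / n_runs))
    t_abs = times[absorbed]
    t_hat = float(t_abs.mean()) if t_abs.size else np.nan
    t_se = float(t_abs.std(ddof=1) / np.sqrt(t_abs.size)) if t_abs.size > 1 else np.nan
    t_fix = times[fixed]
    tau_hat = float(t_fix.mean()) if t_fix.size else np.nan
    tau_se = float(t_fix.std(ddof=1) / np.sqrt(t_fix.size)) if t_fix.size > 1 else np.nan
    return EnsembleEstimate(
        phi_hat=float(phi_hat), phi_se=phi_se, t_hat=t_hat, t_se=t_se,
        tau_hat=tau_hat, tau_se=tau_se, n_runs=n_runs, n_fixed=int(fixed.sum()),
        n_unabsorbed=int(n_runs - absorbed.sum()), seed=seed,
    )


def estimate_fixation(model: BirthDeathModel, chain: EnvironmentChainDiscrete,
                      i0: int, sigma0: SigmaPolicy, n_runs: int, seed: int,
                      max_steps: int = 100_000_000) -> EnsembleEstimate:
    """Ensemble estimate of fixation probability and mean times (discrete).

    ``sigma0`` is a required policy: an environment label, or ``"stationary"``
    to draw the initial environment from the chain's stationary occupancy.
    """
    if n_runs <= 0:
        raise ValueError("n_runs must be positive")
    if not model.absorbing:
        raise ValueError("fixation estimation requires an absorbing (u=0) model")
    s0_arr = _sigma0_array(sigma0, model, chain, seed, n_runs)
    seeds = _run_seeds(seed, n_runs)
    absorbed, fixed, steps = _engine.discrete_ensemble_fixation(
        model.t_plus, model.t_minus, _mu_cum(chain), int(i0), s0_arr, seeds,
        int(max_steps),
    )
    return _summarise(absorbed, fixed, steps.astype(float), n_runs, seed)


def estimate_fixation_ct(model: BirthDeathModel,
                         chain: EnvironmentChainContinuous,
                         i0: int, sigma0: SigmaPolicy, n_runs: int, seed: int,
                         t_max: float = 1e12,
                         max_events: int = 100_000_000) -> EnsembleEstimate:
    """Ensemble estimate of fixation statistics for the continuous-time model."""
    if n_runs <= 0:
        raise ValueError("n_runs must be positive")
    if not model.absorbing:
        raise ValueError("fixation estimation requires an absorbing model")
    s0_arr = _sigma0_array(sigma0, model, chain, seed, n_runs)
    seeds = _run_seeds(seed, n_runs)
    rates = chain.rates.copy()
    np.fill_diagonal(rates, 0.0)
    absorbed, fixed, t_abs = _engine.gillespie_ensemble_fixation(
        model.t_plus, model.t_minus, rates, rates.sum(axis=1), int(i0),
        s0_arr, seeds, float(t_max), int(max_events),
    )
    return _summarise(absorbed, fixed, t_abs, n_runs, seed)


def ensemble_distribution(model: BirthDeathModel,
                          chain: EnvironmentChainDiscrete,
                          n_runs: int, T_generations: float, seed: int,
                          i0: int = 0, sigma0: SigmaPolicy = "stationary",
                          sample_every_generations: float = 1.0,
                          ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical distributions Q_i(t) of a mutation model over [0, T].

    Runs ``n_runs`` replicas for ``T_generations * N`` elementary steps and
    records the ensemble distribution over ``i`` every
    ``sample_every_generations`` generations.  Returns ``(times_in_
    generations, Q, env_occupancy)`` where ``Q[t]`` is the distribution at
    the t-th sample and ``env_occupancy`` is the empirical occupancy of the
    environment states over all samples.
    """
    if model.absorbing:
        raise ValueError("ensemble_distribution requires a mutation (u>0) model")
    N = model.N
    n_steps = int(round(T_generations * N))
    sample_every = max(1, int(round(sample_every_generations * N)))
    s0_arr = _sigma0_array(sigma0, model, chain, seed, n_runs)
    seeds = _run_seeds(seed, n_runs)
    counts, env_counts = _engine.discrete_ensemble_histogram(
        model.t_plus, model.t_minus, _mu_cum(chain), int(i0), s0_arr, seeds,
        n_steps, sample_every,
    )
    Q = counts / n_runs
    times = (np.arange(1, Q.shape[0] + 1) * sample_every) / N
    occupancy = env_counts / env_counts.sum()
    return times, Q, occupancy
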