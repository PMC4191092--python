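import numpy as np
import pytest

from switchfix.env_model import (two_env_chain, validate_continuous_chain,
                                 stationary_occupancy)
from switchfix.fixation_continuous import solve_fixation_ct
from switchfix.fixation_discrete import assemble_step_kernel, solve_fixation
from switchfix.game_model import GameSpec, birth_death_model
from switchfix.simulate import (ensemble_distribution, estimate_fixation,
                                estimate_fixation_ct, run_discrete,
                                run_gillespie)
from switchfix.stationary import stationary_exact, time_averaged_distance


def _small_setup(beta=0.5, N=20, u=0.0):
    spec = GameSpec.switching_game(b=0.5, c=0.9, beta=beta, N=N, u=u)
    return birth_death_model(spec), two_env_chain(0.05, 0.02)


class TestTrajectories:
    def test_identical_seeds_reproduce_bit_identical_series(self, warm_engine):
        model, chain = _small_setup()
        a = run_discrete(model, chain, i0=5, sigma0=+1, seed=42, max_steps=5000)
        b = run_discrete(model, chain, i0=5, sigma0=+1, seed=42, max_steps=5000)
        assert np.array_equal(a.i, b.i) and np.array_equal(a.sigma, b.sigma)
        c = run_discrete(model, chain, i0=5, sigma0=+1, seed=43, max_steps=5000)
        assert not np.array_equal(a.i, c.i)

    def test_started_at_extinction_absorbs_immediately(self, warm_engine):
        model, chain = _small_setup()
        traj = run_discrete(model, chain, i0=0, sigma0=-1, seed=1)
        assert traj.absorbed and traj.absorbing_state == 0
        assert traj.absorption_time == 0.0 and len(traj.i) == 1

    def test_states_stay_in_range_and_absorption_flagged(self, warm_engine):
        model, chain = _small_setup()
        traj = run_discrete(model, chain, i0=3, sigma0=-1, seed=7)
        assert traj.i.min() >= 0 and traj.i.max() <= 20
        assert traj.absorbed
        assert traj.i[-1] in (0, 20)

    def test_max_steps_exhaustion_is_flagged_not_raised(self, warm_engine):
        model, chain = _small_setup()
        traj = run_discrete(model, chain, i0=10, sigma0=+1, seed=3, max_steps=5)
        assert not traj.absorbed
        assert traj.absorbing_state is None

    def test_one_step_frequencies_match_kernel_row(self, warm_engine):
        """Empirical one-step frequencies from a fixed (i, sigma), generated
        by the jitted engine itself, agree with the step-kernel row within
        binomial error."""
        from switchfix._engine import discrete_ensemble_histogram
        spec = GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=20, u=0.02)
        model = birth_death_model(spec)  # mutation model: no absorption cutoffs
        chain = two_env_chain(0.3, 0.1)
        kernel = assemble_step_kernel(model, chain)
        i0, s0 = 10, 0
        n = 200_000
        seeds = np.random.SeedSequence(99).generate_state(n, dtype=np.uint32)
        mu_cum = np.cumsum(chain.mu, axis=1)
        mu_cum[:, -1] = 1.0 + 1e-12
        counts, env_counts = discrete_ensemble_histogram(
            model.t_plus, model.t_minus, mu_cum, i0,
            np.full(n, s0, dtype=np.int64), seeds, 1, 1)
        row = kernel.matrix[kernel.index(i0, s0)].toarray().ravel()
        for di in (-1, 0, 1):
            p = sum(row[kernel.index(i0 + di, s2)] for s2 in range(2))
            freq = counts[0, i0 + di] / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 4 * se + 1e-12
        for s2 in range(2):
            p = chain.mu[s0, s2]
            freq = env_counts[s2] / n
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 4 * se + 1e-12

    def test_gillespie_zero_switching_is_pure_birth_death(self, warm_engine):
        spec = GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=15)
        model = birth_death_model(spec).as_continuous()
        chain = validate_continuous_chain(np.zeros((1, 1)))
        from switchfix.game_model import BirthDeathModel
        single = BirthDeathModel(N=15, t_plus=model.t_plus[:1],
                                 t_minus=model.t_minus[:1],
                                 time_convention="continuous", labels=(0,))
        traj = run_gillespie(single, chain, i0=5, sigma0=0, seed=5, t_max=1e9)
        assert np.all(traj.sigma == 0)
        assert traj.absorbed
        assert np.all(np.diff(traj.times) > 0)


class TestEnsembleEstimators:
    def test_neutral_fixation_probability_is_one_over_N(self, warm_engine):
        model, chain = _small_setup(beta=0.0, N=50)
        est = estimate_fixation(model, chain, i0=1, sigma0=+1, n_runs=100_000,
                                seed=12)
        assert abs(est.phi_hat - 0.02) < 3 * est.phi_se

    def test_estimates_match_exact_solver_within_3_se(self, warm_engine):
        model, chain = _small_setup(N=20)
        sol = solve_fixation(model, chain)
        for s0, s in ((+1, 0), (-1, 1)):
            est = estimate_fixation(model, chain, i0=1, sigma0=s0,
                                    n_runs=40_000, seed=21)
            assert abs(est.phi_hat - sol.phi[1, s]) < 3 * est.phi_se
            assert abs(est.tau_hat - sol.t_cond[1, s]) < 3 * est.tau_se
            assert abs(est.t_hat - sol.t_uncond[1, s]) < 3 * est.t_se

    def test_all_runs_absorb_without_mutation(self, warm_engine):
        model, chain = _small_setup(N=20)
        est = estimate_fixation(model, chain, i0=10, sigma0=-1, n_runs=5000,
                                seed=2, max_steps=10_000_000)
        assert est.n_unabsorbed == 0

    def test_gillespie_ensemble_matches_ct_solver(self, warm_engine):
        spec = GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=12)
        model = birth_death_model(spec).as_continuous()
        chain = validate_continuous_chain(np.array([[0.0, 0.05], [0.02, 0.0]]))
        sol = solve_fixation_ct(model, chain)
        est = estimate_fixation_ct(model, chain, i0=1, sigma0=+1,
                                   n_runs=30_000, seed=8)
        assert abs(est.phi_hat - sol.phi[1, 0]) < 3 * est.phi_se
        assert abs(est.tau_hat - sol.t_cond[1, 0]) < 3 * est.tau_se

    def test_stationary_sigma0_policy_and_reproducibility(self, warm_engine):
        model, chain = _small_setup(N=10)
        a = estimate_fixation(model, chain, i0=1, sigma0="stationary",
                              n_runs=2000, seed=4)
        b = estimate_fixation(model, chain, i0=1, sigma0="stationary",
                              n_runs=2000, seed=4)
        assert a == b

    def test_zero_runs_rejected(self):
        model, chain = _small_setup(N=10)
        with pytest.raises(ValueError, match="n_runs"):
            estimate_fixation(model, chain, i0=1, sigma0=+1, n_runs=0, seed=1)


class TestEnsembleDistribution:
    def test_converges_to_exact_stationary_law(self, warm_engine):
        spec = GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=20, u=0.05)
        model = birth_death_model(spec)
        chain = two_env_chain(0.05, 0.05)
        rho = stationary_exact(model, chain).rho_marginal
        d_prev = None
        for n_runs in (200, 2000):
            _, Q, _ = ensemble_distribution(model, chain, n_runs=n_runs,
                                            T_generations=300, seed=5)
            d = time_averaged_distance(Q, rho)
            if d_prev is not None:
                assert d < d_prev
            d_prev = d
        assert d_prev < 0.03

    def test_environment_occupancy_matches_telegraph_formula(self, warm_engine):
        spec = GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=10, u=0.05)
        model = birth_death_model(spec)
        chain = two_env_chain(0.02, 0.04)
        _, _, occ = ensemble_distribution(model, chain, n_runs=400,
                                          T_generations=500, seed=9)
        expected = stationary_occupancy(chain)
        assert np.abs(occ - expected).max() < 0.02

    def test_requires_mutation_model(self, warm_engine):
        model, chain = _small_setup(N=10)
        with pytest.raises(ValueError, match="mutation"):
            ensemble_distribution(model, chain, n_runs=10, T_generations=10, seed=1)
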