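import numpy as np
import pytest

from oracles import (fundamental_oracle, random_absorbing_model,
                     random_stochastic_matrix, single_env_closed_form)
from switchfix.env_model import (SingularSwitchingError, two_env_chain,
                                 validate_discrete_chain)
from switchfix.fixation_discrete import (assemble_step_kernel,
                                         conditional_times,
                                         fixation_probabilities,
                                         recursion_solver, solve_fixation,
                                         unconditional_times)
from switchfix.game_model import BirthDeathModel, GameSpec, birth_death_model


def _model(tp, tm):
    return BirthDeathModel(N=tp.shape[1] - 1, t_plus=tp, t_minus=tm)


class TestStepKernel:
    def test_single_environment_reduces_to_tridiagonal(self, rng):
        tp, tm = random_absorbing_model(rng, 6, 1)
        kernel = assemble_step_kernel(_model(tp, tm),
                                      validate_discrete_chain([[1.0]]))
        dense = kernel.matrix.toarray()
        assert np.allclose(dense, np.triu(np.tril(dense, 1), -1))

    def test_rows_sum_to_one(self, rng):
        tp, tm = random_absorbing_model(rng, 5, 2)
        kernel = assemble_step_kernel(_model(tp, tm), two_env_chain(0.3, 0.1))
        assert np.allclose(kernel.matrix.sum(axis=1), 1.0, atol=1e-14)

    def test_boundary_rows_only_move_the_environment(self, rng):
        tp, tm = random_absorbing_model(rng, 5, 2)
        chain = two_env_chain(0.3, 0.1)
        kernel = assemble_step_kernel(_model(tp, tm), chain)
        dense = kernel.matrix.toarray()
        for s in range(2):
            row = dense[kernel.index(0, s)]
            assert np.allclose(row[[kernel.index(0, 0), kernel.index(0, 1)]],
                               chain.mu[s])
            assert row.sum() == pytest.approx(1.0)

    def test_no_jumps_beyond_one_step(self, rng):
        tp, tm = random_absorbing_model(rng, 7, 3)
        kernel = assemble_step_kernel(
            _model(tp, tm),
            validate_discrete_chain(random_stochastic_matrix(rng, 3)))
        dense = kernel.matrix.toarray()
        for i in range(8):
            for j in range(8):
                if abs(i - j) > 1:
                    block = dense[i * 3:(i + 1) * 3, j * 3:(j + 1) * 3]
                    assert np.all(block == 0)


class TestFixationProbabilities:
    def test_neutral_model_gives_i_over_N(self):
        spec = GameSpec.switching_game(b=0.5, c=0.9, beta=0.0, N=12)
        phi, _ = fixation_probabilities(birth_death_model(spec),
                                        two_env_chain(0.2, 0.05))
        expected = np.arange(13)[:, None] / 12
        assert np.abs(phi - expected).max() < 1e-10

    def test_single_environment_matches_classical_closed_form(self, rng):
        tp, tm = random_absorbing_model(rng, 10, 1)
        phi, _ = fixation_probabilities(_model(tp, tm),
                                        validate_discrete_chain([[1.0]]))
        phi_cf, _, _ = single_env_closed_form(tp[0], tm[0])
        assert np.abs(phi[:, 0] - phi_cf).max() < 1e-10

    def test_matches_fundamental_matrix_oracle(self, rng):
        tp, tm = random_absorbing_model(rng, 8, 2)
        mu = random_stochastic_matrix(rng, 2)
        phi, diag = fixation_probabilities(_model(tp, tm),
                                           validate_discrete_chain(mu))
        phi_o, _, _ = fundamental_oracle(tp, tm, mu)
        assert np.abs(phi - phi_o).max() < 1e-10
        assert diag.residual <= 1e-10

    def test_monotone_in_initial_mutant_count(self, rng):
        for _ in range(20):
            tp, tm = random_absorbing_model(rng, 9, 2)
            mu = random_stochastic_matrix(rng, 2)
            phi, _ = fixation_probabilities(_model(tp, tm),
                                            validate_discrete_chain(mu))
            assert np.all(np.diff(phi, axis=0) >= -1e-12)

    def test_requires_absorbing_model(self):
        spec = GameSpec.switching_game(b=0.5, c=0.9, beta=0.5, N=8, u=0.02)
        with pytest.raises(ValueError, match="absorbing"):
            fixation_probabilities(birth_death_model(spec), two_env_chain(0.1, 0.1))


class TestFixationTimes:
    def test_boundary_times_are_zero(self, rng):
        tp, tm = random_absorbing_model(rng, 6, 2)
        t, _ = unconditional_times(_model(tp, tm), two_env_chain(0.2, 0.3))
        assert np.all(t[[0, -1]] == 0)

    def test_two_state_neutral_geometric_mean(self):
        # N=2, single environment, T+=T-=1/4: absorption per step prob 1/2
        tp = np.array([[0.0, 0.25, 0.0]])
        tm = np.array([[0.0, 0.25, 0.0]])
        t, _ = unconditional_times(_model(tp, tm), validate_discrete_chain([[1.0]]))
        assert t[1, 0] == pytest.approx(2.0, abs=1e-10)

    def test_times_match_fundamental_matrix_oracle(self, rng):
        tp, tm = random_absorbing_model(rng, 8, 2)
        mu = random_stochastic_matrix(rng, 2)
        model = _model(tp, tm)
        chain = validate_discrete_chain(mu)
        _, t_o, tau_o = fundamental_oracle(tp, tm, mu)
        t, _ = unconditional_times(model, chain)
        tau, _ = conditional_times(model, chain)
        assert np.abs(t - t_o).max() < 1e-9
        assert np.nanmax(np.abs(tau - tau_o)) < 1e-9

    def test_single_environment_conditional_closed_form(self, rng):
        tp, tm = random_absorbing_model(rng, 8, 1)
        model = _model(tp, tm)
        chain = validate_discrete_chain([[1.0]])
        tau, _ = conditional_times(model, chain)
        _, t1_cf, tau1_cf = single_env_closed_form(tp[0], tm[0])
        t, _ = unconditional_times(model, chain)
        assert t[1, 0] == pytest.approx(t1_cf, rel=1e-9)
        assert tau[1, 0] == pytest.approx(tau1_cf, rel=1e-9)

    def test_conditional_time_at_fixation_boundary_is_zero(self, rng):
        tp, tm = random_absorbing_model(rng, 5, 2)
        tau, _ = conditional_times(_model(tp, tm), two_env_chain(0.4, 0.2))
        assert np.all(tau[-1] == 0)
        assert np.all(np.isnan(tau[0]))


class TestStructureInvariants:
    def test_environment_relabeling_equivariance(self, rng):
        tp, tm = random_absorbing_model(rng, 7, 3)
        mu = random_stochastic_matrix(rng, 3)
        perm = np.array([2, 0, 1])
        sol = solve_fixation(_model(tp, tm), validate_discrete_chain(mu))
        sol_p = solve_fixation(_model(tp[perm], tm[perm]),
                               validate_discrete_chain(mu[np.ix_(perm, perm)]))
        assert np.allclose(sol.phi[:, perm], sol_p.phi, atol=1e-12)
        assert np.allclose(sol.t_uncond[:, perm], sol_p.t_uncond, atol=1e-9)

    def test_frozen_environment_reduces_to_single_environment_slices(self, rng):
        tp, tm = random_absorbing_model(rng, 8, 2)
        sol = solve_fixation(_model(tp, tm), validate_discrete_chain(np.eye(2)))
        for s in range(2):
            single = solve_fixation(_model(tp[s:s + 1], tm[s:s + 1]),
                                    validate_discrete_chain([[1.0]]))
            assert np.allclose(sol.phi[:, s], single.phi[:, 0], atol=1e-10)
            assert np.allclose(sol.t_uncond[:, s], single.t_uncond[:, 0], atol=1e-8)

    def test_generation_units_are_steps_over_N(self, rng):
        tp, tm = random_absorbing_model(rng, 6, 2)
        sol = solve_fixation(_model(tp, tm), two_env_chain(0.2, 0.1))
        assert np.allclose(sol.t_uncond_generations * 6, sol.t_uncond)


class TestRecursionSolver:
    def test_single_environment_matches_direct_solver(self, rng):
        tp, tm = random_absorbing_model(rng, 9, 1)
        model = _model(tp, tm)
        chain = validate_discrete_chain([[1.0]])
        direct = solve_fixation(model, chain)
        rec = recursion_solver(model, chain)
        assert np.abs(direct.phi - rec.phi).max() < 1e-10

    def test_agrees_with_direct_solver_on_sweep_parameters(self, sweep_model):
        """Cross-solver agreement at N=50, beta=0.5 over a p_plus grid."""
        for p_plus in [1e-3, 1e-2, 1e-1, 0.9]:
            chain = two_env_chain(p_plus, 0.01)
            direct = solve_fixation(sweep_model, chain)
            rec = recursion_solver(sweep_model, chain)
            assert np.abs(direct.phi - rec.phi).max() < 1e-8
            assert np.abs(direct.t_uncond - rec.t_uncond).max() < 1e-8
            assert np.nanmax(np.abs(direct.t_cond - rec.t_cond)) < 1e-8

    def test_singular_switching_matrix_raises(self, sweep_model):
        with pytest.raises(SingularSwitchingError):
            recursion_solver(sweep_model, two_env_chain(0.5, 0.5))
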