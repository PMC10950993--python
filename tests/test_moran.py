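"""Unit and property tests for the stochastic Moran engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tumoran import (
    DegenerateSelectionError,
    FitnessParams,
    InvalidStateError,
    MutationParams,
    PopulationState,
    SimulationConfig,
    simulate,
    simulate_ensemble,
    step,
    transition_probabilities,
)
from tumoran.moran import EVENT_NAMES, _EVENT_DELTAS

from conftest import random_valid_states


class TestTransitionProbabilities:
    def test_two_type_advantaged_example(self):
        # N=100, 10 cancer cells at fitness 5: birth weight 50/140, death 90/100
        dist = transition_probabilities(
            PopulationState(90, 10), FitnessParams(f_h=1, f_c=5), MutationParams(0)
        )
        assert dist["c_birth_h_death"] == pytest.approx(4500 / 14000)
        assert dist["h_birth_c_death"] == pytest.approx(900 / 14000)
        assert dist["no_change"] == pytest.approx(1 - 5400 / 14000)

    def test_all_healthy_state_is_absorbing(self):
        dist = transition_probabilities(
            PopulationState(100, 0, 0), FitnessParams(1, 2, 3), MutationParams(0.5)
        )
        assert dist["no_change"] == pytest.approx(1.0)
        for name in EVENT_NAMES[:-1]:
            assert dist[name] == 0.0

    def test_neutral_symmetry(self):
        dist = transition_probabilities(
            PopulationState(50, 50), FitnessParams(1, 1, 1), MutationParams(0)
        )
        assert dist["c_birth_h_death"] == pytest.approx(0.25)
        assert dist["h_birth_c_death"] == pytest.approx(0.25)
        assert dist["no_change"] == pytest.approx(0.5)

    def test_marginal_mutation_probability(self):
        # total mutation mass r_m * N_c f_c / W
        dist = transition_probabilities(
            PopulationState(900, 100, 0),
            FitnessParams(f_h=1, f_c=1.1),
            MutationParams(0.01),
        )
        total_mut = sum(dist[n] for n in EVENT_NAMES if n.startswith("mut_"))
        assert total_mut == pytest.approx(0.01 * 110 / 1010)

    def test_normalisation_over_many_random_states(self, rng):
        for counts, fit, r_m in random_valid_states(rng, 10_000):
            state = PopulationState(*counts)
            dist = transition_probabilities(
                state, FitnessParams(*fit), MutationParams(r_m)
            )
            assert abs(dist.total() - 1.0) < 1e-12
            assert min(dist.probs) >= 0.0

    def test_neutral_one_step_martingale(self, rng):
        # With equal fitness and no mutation, E[dN_c] = 0 exactly.
        for counts, _, _ in random_valid_states(rng, 200):
            state = PopulationState(*counts)
            dist = transition_probabilities(
                state, FitnessParams(1.0, 1.0, 1.0), MutationParams(0)
            )
            drift = sum(
                p * _EVENT_DELTAS[name][1] for name, p in zip(EVENT_NAMES, dist.probs)
            )
            assert abs(drift) < 1e-14

    def test_degenerate_selection_raises(self):
        with pytest.raises(DegenerateSelectionError):
            transition_probabilities(
                PopulationState(0, 5, 5), FitnessParams(1.0, 0.0, 0.0), MutationParams(0)
            )

    def test_empty_population_rejected(self):
        with pytest.raises(InvalidStateError):
            PopulationState(0, 0, 0)


class TestStep:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_conservation_and_single_cell_moves(self, seed):
        rng = np.random.default_rng(seed)
        state = PopulationState(70, 20, 10)
        new = step(state, FitnessParams(1, 1.3, 2.0), MutationParams(0.1), rng)
        assert new.N == state.N
        assert new.division_index == state.division_index + 1
        deltas = np.array(new.as_tuple()) - np.array(state.as_tuple())
        assert np.all(np.abs(deltas) <= 1) and deltas.sum() == 0

    def test_fixated_cancer_without_mutation_never_changes(self, rng):
        state = PopulationState(0, 100, 0)
        for _ in range(20):
            new = step(state, FitnessParams(1, 2), MutationParams(0), rng)
            assert new.as_tuple() == state.as_tuple()
            state = new

    def test_mutation_event_with_healthy_dier_creates_mutant(self):
        # r_m=1 and a dominant cancer fitness force a mutant birth; with a
        # large healthy pool the dier is almost surely healthy.
        state = PopulationState(999, 1, 0)
        fitness = FitnessParams(f_h=1e-12, f_c=1.0)
        hits = 0
        rng = np.random.default_rng(0)
        for _ in range(50):
            new = step(state, fitness, MutationParams(1.0), rng)
            assert new.n_mutant == 1  # every cancer birth diverts to a mutant
            if new.n_healthy == state.n_healthy - 1:
                # healthy dier: cancer count untouched
                assert new.n_cancer == 1
                hits += 1
            else:
                # the lone cancer cell was chosen to die
                assert new.n_cancer == 0
        assert hits > 40


class TestSimulate:
    def test_all_healthy_stays_constant(self):
        cfg = SimulationConfig.from_counts(N=50, M=200, n_cancer=0, seed=1)
        traj = simulate(cfg, FitnessParams(1, 2), MutationParams(0))
        assert np.all(traj.states[:, 0] == 50)
        assert traj.absorbed_at == 0

    def test_identical_seed_gives_identical_trajectory(self):
        cfg = SimulationConfig.from_counts(N=100, M=500, n_cancer=10, seed=42)
        a = simulate(cfg, FitnessParams(1, 1.5), MutationParams(0.01))
        b = simulate(cfg, FitnessParams(1, 1.5), MutationParams(0.01))
        assert np.array_equal(a.states, b.states)

    def test_conservation_and_stepwise_moves_along_trajectory(self):
        cfg = SimulationConfig.from_counts(N=100, M=2000, n_cancer=10, seed=7)
        traj = simulate(cfg, FitnessParams(1, 2, 3), MutationParams(0.05))
        assert np.all(traj.states.sum(axis=1) == 100)
        diffs = np.diff(traj.states, axis=0)
        assert np.max(np.abs(diffs)) <= 1

    def test_advantaged_cancer_sweeps(self):
        cfg = SimulationConfig.from_counts(N=100, M=3000, n_cancer=10, seed=3)
        traj = simulate(cfg, FitnessParams(1, 5), MutationParams(0))
        assert traj.states[-1, 1] == 100  # fixation well within M
        assert traj.absorbed_at is not None

    def test_absorbed_trajectory_padded_to_full_length(self):
        cfg = SimulationConfig.from_counts(N=20, M=5000, n_cancer=10, seed=5)
        traj = simulate(cfg, FitnessParams(1, 10), MutationParams(0))
        assert len(traj) == 5001
        tail = traj.states[traj.absorbed_at :]
        assert np.all(tail == tail[0])


class TestEnsemble:
    def test_single_replicate_matches_mean_with_zero_std(self):
        cfg = SimulationConfig.from_counts(N=60, M=300, n_cancer=6, n_total=1, seed=9)
        ens = simulate_ensemble(cfg, FitnessParams(1, 1.2), MutationParams(0))
        assert np.all(ens.std == 0)
        traj = simulate(cfg, FitnessParams(1, 1.2), MutationParams(0))
        # same base seed drives both code paths deterministically
        assert ens.mean.shape == (301, 3)

    def test_neutral_mean_stays_near_initial_and_std_grows(self):
        cfg = SimulationConfig.from_counts(N=100, M=400, n_cancer=10, n_total=400, seed=11)
        ens = simulate_ensemble(cfg, FitnessParams(1, 1), MutationParams(0))
        # martingale: mean N_c stays at 10 within Monte-Carlo error
        se_final = ens.std[-1, 1] / np.sqrt(400)
        assert abs(ens.mean[-1, 1] - 10) < 4 * max(se_final, 1e-9)
        assert ens.std[-1, 1] > ens.std[10, 1]

    def test_seed_determinism(self):
        cfg = SimulationConfig.from_counts(N=80, M=500, n_cancer=8, n_total=20, seed=2)
        a = simulate_ensemble(cfg, FitnessParams(1, 1.4), MutationParams(0.01))
        b = simulate_ensemble(cfg, FitnessParams(1, 1.4), MutationParams(0.01))
        assert np.array_equal(a.final_states, b.final_states)
        assert np.array_equal(a.mean, b.mean)

    @pytest.mark.parametrize("i,r", [(5, 1.0), (5, 2.0), (25, 1.1)])
    def test_two_type_fixation_probability_matches_closed_form(self, i, r):
        # classical Moran fixation probability (1 - r^-i) / (1 - r^-N)
        N = 50
        cfg = SimulationConfig.from_counts(N=N, M=60_000, n_cancer=i, n_total=800, seed=13)
        ens = simulate_ensemble(cfg, FitnessParams(1.0, r), MutationParams(0))
        expected = i / N if r == 1.0 else (1 - r**-i) / (1 - r**-N)
        p_hat = ens.fixation_fraction("cancer")
        se = np.sqrt(expected * (1 - expected) / 800)
        assert abs(p_hat - expected) < 3 * max(se, 1e-6)
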