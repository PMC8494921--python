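import numpy as np
import pytest
from scipy import stats

from culturesim import (
    CandidateSet,
    PayoffPool,
    PopulationState,
    SimulationConfig,
    apply_production_error,
    critical_choice,
    critical_choice_probabilities,
    generate_payoff_pool,
    initialize_population,
    innovate_variant,
    run_simulation,
    run_time_step,
    uncritical_choice,
    update_agent,
)
from culturesim.core import _payoff_transform

from conftest import make_config


class TestPayoffPool:
    def test_transform_values(self):
        # round(2 x^2) + 1: x=0 -> 1, x=3 -> 19
        assert _payoff_transform(np.array([0.0, 3.0])).tolist() == [1, 19]
        # half-away-from-zero rounding at 2x^2 = 0.5 exactly
        assert _payoff_transform(np.array([0.5])).tolist() == [2]

    def test_generated_pool_invariants(self, rng):
        pool = generate_payoff_pool(100, 1.0, rng)
        assert pool.size == 100
        assert pool.payoffs.min() >= 1
        assert pool.payoffs.dtype == np.int64

    def test_typical_maximum_payoff_near_50(self, rng):
        maxima = [generate_payoff_pool(100, 1.0, rng).payoffs.max() for _ in range(2000)]
        assert 48 <= np.median(maxima) <= 52

    def test_invalid_parameters(self, rng):
        with pytest.raises(ValueError):
            generate_payoff_pool(0, 1.0, rng)
        with pytest.raises(ValueError):
            generate_payoff_pool(10, 0.0, rng)
        with pytest.raises(ValueError):
            PayoffPool(np.array([1, 0, 3]))


class TestInitialisation:
    def test_single_variant_pool(self, rng):
        config = make_config(pool_size=1, population_size=5)
        state = initialize_population(config, PayoffPool([4]), rng)
        assert (state.variants == 0).all()

    def test_initial_distribution_uniform(self, rng):
        config = make_config(pool_size=100, population_size=100)
        pool = generate_payoff_pool(100, 1.0, rng)
        draws = np.concatenate(
            [initialize_population(config, pool, rng).variants for _ in range(1000)]
        )
        counts = np.bincount(draws, minlength=100)
        assert stats.chisquare(counts).pvalue > 0.001


class TestInnovation:
    def test_single_variant_pool(self, rng):
        assert innovate_variant(PayoffPool([2]), rng) == 0

    def test_uniform_over_pool(self, rng):
        pool = PayoffPool(np.full(100, 1))
        draws = np.array([innovate_variant(pool, rng) for _ in range(100_000)])
        assert draws.min() >= 0 and draws.max() < 100
        counts = np.bincount(draws, minlength=100)
        assert stats.chisquare(counts).pvalue > 0.001


class TestCriticalChoice:
    def test_worked_example_probabilities(self):
        candidates = CandidateSet((0, 10), (1, 6), (2, 4))
        probs = critical_choice_probabilities(candidates)
        assert probs.tolist() == [0.5, 0.3, 0.2]

    @pytest.mark.parametrize(
        "payoffs", [(10, 6, 4), (5, 5, 5), (1, 1, 2), (1, 37, 4)]
    )
    def test_empirical_frequencies_match_exact(self, rng, payoffs):
        """Roulette frequencies match payoff proportions within 3 SE at 100k draws."""
        candidates = CandidateSet((0, payoffs[0]), (1, payoffs[1]), (2, payoffs[2]))
        expected = critical_choice_probabilities(candidates)
        n = 100_000
        draws = np.array([critical_choice(candidates, rng) for _ in range(n)])
        freqs = np.bincount(draws, minlength=3) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(freqs - expected) <= 3 * se + 1e-9).all()

    def test_duplicate_ids_add_mass(self, rng):
        # own and model hold the same variant: its total mass is 2/3
        candidates = CandidateSet((5, 1), (5, 1), (9, 1))
        draws = np.array([critical_choice(candidates, rng) for _ in range(30_000)])
        share = (draws == 5).mean()
        assert abs(share - 2 / 3) < 0.01

    def test_rejects_nonpositive_payoff(self, rng):
        with pytest.raises(ValueError):
            critical_choice(CandidateSet((0, 0), (1, 6), (2, 4)), rng)


class TestUncriticalChoice:
    candidates = CandidateSet((7, 3), (42, 1), (13, 50))

    @pytest.mark.parametrize(
        "learner_type, expected",
        [("maintainer", 7), ("copier", 42), ("innovator", 13)],
    )
    def test_defaults_ignore_payoffs(self, learner_type, expected):
        assert uncritical_choice(learner_type, self.candidates) == expected

    def test_degenerate_identical_candidates(self):
        same = CandidateSet((4, 2), (4, 2), (4, 2))
        assert uncritical_choice("innovator", same) == 4

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            uncritical_choice("imitator", self.candidates)


class TestProductionError:
    def test_zero_rate_is_identity(self, rng, small_pool):
        assert all(
            apply_production_error(2, 0.0, small_pool, rng) == 2 for _ in range(100)
        )

    def test_full_rate_resamples_uniformly(self, rng):
        pool = PayoffPool(np.full(50, 1))
        draws = np.array(
            [apply_production_error(3, 1.0, pool, rng) for _ in range(100_000)]
        )
        counts = np.bincount(draws, minlength=50)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_error_fraction_matches_rate(self, rng):
        pool = PayoffPool(np.full(100, 1))
        n = 200_000
        changed = sum(apply_production_error(0, 0.02, pool, rng) != 0 for _ in range(n))
        # an error keeps the original id with probability 1/pool_size
        expected = 0.02 * (1 - 1 / 100)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(changed / n - expected) <= 4 * se


class TestAgentUpdate:
    def test_uncritical_maintainer_is_identity(self, rng, small_pool):
        config = make_config(payoff_bias=0.0, error_rate=0.0, pool_size=small_pool.size)
        state = PopulationState(np.array([2, 4, 1, 0, 3] * 2), small_pool)
        before = state.variants.copy()
        for i in range(state.n_agents):
            assert update_agent(i, state, config, lambda i, r: (i + 1) % 10, rng) == before[i]
        assert (state.variants == before).all()

    def test_critical_branch_frequency(self, rng, small_pool):
        """With b=0.2 and a maintainer default, the model selector fires on
        exactly the critical updates, so its call rate estimates b."""
        config = make_config(payoff_bias=0.2, error_rate=0.0, pool_size=small_pool.size)
        calls = 0

        def counting_selector(i, r):
            nonlocal calls
            calls += 1
            return (i + 1) % 4

        state = PopulationState(np.array([0, 1, 2, 3]), small_pool)
        n = 200_000
        for k in range(n):
            update_agent(k % 4, state, config, counting_selector, rng)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(calls / n - 0.2) <= 4 * se


class TestTimeStep:
    def test_sequential_copying_hand_trace(self, rng):
        """N=2 uncritical copiers without error: agent 0 adopts agent 1's
        initial variant, then agent 1 copies agent 0's *new* variant — both
        end the step holding agent 1's initial variant."""
        pool = PayoffPool(np.array([2, 9]))
        config = make_config(
            payoff_bias=0.0, learner_type="copier", error_rate=0.0,
            pool_size=2, population_size=2,
        )
        state = PopulationState(np.array([0, 1]), pool)
        run_time_step(state, config, lambda i, r: 1 - i, rng)
        assert state.variants.tolist() == [1, 1]

    def test_maintainers_are_a_fixed_point(self, rng, small_pool):
        config = make_config(payoff_bias=0.0, error_rate=0.0,
                             pool_size=small_pool.size, population_size=6)
        state = PopulationState(np.array([0, 1, 2, 3, 4, 0]), small_pool)
        before = state.variants.copy()
        for _ in range(5):
            run_time_step(state, config, lambda i, r: (i + 1) % 6, rng)
        assert (state.variants == before).all()

    def test_step_conserves_population_and_pool(self, rng, small_pool):
        config = make_config(payoff_bias=0.5, learner_type="copier",
                             pool_size=small_pool.size, population_size=8)
        state = initialize_population(config, small_pool, rng)
        pool_before = state.pool.payoffs.copy()
        run_time_step(state, config, lambda i, r: (i + 3) % 8, rng)
        assert state.n_agents == 8
        assert (state.pool.payoffs == pool_before).all()
        assert ((state.variants >= 0) & (state.variants < small_pool.size)).all()


class TestRunSimulation:
    def test_zero_steps_records_initial_state_only(self):
        trajectory = run_simulation(make_config(n_steps=0))
        assert trajectory.diversity.shape == (1,)
        assert trajectory.mean_payoff.shape == (1,)

    def test_frozen_population_has_constant_trajectory(self):
        config = make_config(payoff_bias=0.0, learner_type="maintainer",
                             error_rate=0.0, n_steps=200)
        trajectory = run_simulation(config)
        assert np.ptp(trajectory.diversity) == 0.0
        assert np.ptp(trajectory.mean_payoff) == 0.0

    def test_seed_determinism(self):
        config = make_config(payoff_bias=0.6, learner_type="copier", seed=99,
                             n_steps=50)
        a, b = run_simulation(config), run_simulation(config)
        assert (a.diversity == b.diversity).all()
        assert (a.mean_payoff == b.mean_payoff).all()
        assert (a.final_state.variants == b.final_state.variants).all()

    def test_structured_run_closure(self):
        config = make_config(population_size=20, structure_sigma=1.0, n_steps=30,
                             learner_type="copier", payoff_bias=0.4)
        trajectory = run_simulation(config)
        variants = trajectory.final_state.variants
        assert ((variants >= 0) & (variants < config.pool_size)).all()

    def test_full_bias_makes_learner_types_identical(self):
        """At b=1 the uncritical default never fires, so all three learner
        types consume the same random stream and produce identical runs."""
        runs = [
            run_simulation(make_config(payoff_bias=1.0, learner_type=t, seed=7,
                                       n_steps=100))
            for t in ("copier", "innovator", "maintainer")
        ]
        for other in runs[1:]:
            assert (runs[0].diversity == other.diversity).all()
            assert (runs[0].mean_payoff == other.mean_payoff).all()

    def test_adaptation_under_full_bias(self):
        """Fully critical small populations reliably climb in mean payoff."""
        improved = 0
        for seed in range(100):
            t = run_simulation(make_config(payoff_bias=1.0, learner_type="copier",
                                           population_size=10, seed=seed))
            improved += t.mean_payoff[-1] > t.mean_payoff[0]
        assert improved >= 95


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"payoff_bias": 1.5},
            {"learner_type": "borrower"},
            {"error_rate": -0.1},
            {"population_size": 1},
            {"structure_sigma": 0.0},
            {"n_steps": -1},
            {"payoff_rate": 0.0},
            {"pool_size": 0},
        ],
    )
    def test_invalid_configs_rejected(self, overrides):
        with pytest.raises(ValueError):
            make_config(**overrides)
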