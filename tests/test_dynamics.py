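"""Evolutionary trial dynamics: lifetimes, selection, transmission, fixation."""

import numpy as np
import pytest

from banditevo import (
    ASOCIAL_FIXATION,
    SOCIAL_FIXATION,
    CognitionConfig,
    EnvironmentConfig,
    EnvironmentState,
    Population,
    SimConfig,
    check_fixation,
    init_naive_agent,
    run_generation,
    run_trial,
    select_reproducers,
    select_teacher,
    step_intergenerational,
)
from conftest import ci99_halfwidth


def make_cfg(**kw):
    env = EnvironmentConfig(
        n_arms=kw.pop("n_arms", 2),
        pi_high=kw.pop("pi_high", 0.9),
        pi_low=kw.pop("pi_low", 0.1),
        u=kw.pop("u", 0.0),
        lifespan=kw.pop("lifespan", 4),
    )
    cog = CognitionConfig(beta=kw.pop("beta", 10.0), n_teachers=kw.pop("n_teachers", 2))
    return SimConfig(n_agents=kw.pop("n_agents", 10), env=env, cognition=cog, **kw)


def pop_with_net(net):
    pop = Population.naive(np.zeros(len(net), dtype=np.int8), 2)
    pop.net[:] = net
    return pop


class TestRunGeneration:
    def test_certain_payoffs_saturate_lifespan(self, rng):
        cfg = make_cfg(pi_high=1.0, pi_low=1.0, lifespan=6)
        pop = Population.naive(np.zeros(10, dtype=np.int8), 2)
        run_generation(pop, EnvironmentState(0), cfg, rng)
        assert np.all(pop.net == 6)

    def test_single_arm_net_payoff_is_binomial(self, rng):
        cfg = make_cfg(n_arms=1, pi_high=0.9, pi_low=0.9, lifespan=20, n_agents=500)
        pop = Population.naive(np.zeros(500, dtype=np.int8), 1)
        run_generation(pop, EnvironmentState(0), cfg, rng)
        # mean of Binomial(20, 0.9) is 18; CI over 500 * 20 draws
        assert abs(pop.net.mean() - 18.0) < 20 * ci99_halfwidth(0.9, 500 * 20)

    def test_each_agent_gains_exactly_lifespan_observations(self, rng):
        cfg = make_cfg(lifespan=1, n_arms=3)
        pop = Population.naive(np.ones(10, dtype=np.int8), 3)
        run_generation(pop, EnvironmentState(1), cfg, rng)
        assert np.all(pop.count.sum(axis=1) == 1)
        assert np.all((pop.net >= 0) & (pop.net <= 1))

    def test_agent_view_matches_scalar_state(self, rng):
        cfg = make_cfg(lifespan=3, n_arms=2)
        pop = Population.naive(np.zeros(4, dtype=np.int8), 2)
        run_generation(pop, EnvironmentState(0), cfg, rng)
        a = pop.agent(0)
        assert a.net_payoff == pop.net[0]
        assert np.all(a.count == pop.count[0])


class TestSelectReproducers:
    def test_degenerate_payoffs_select_sole_earner(self, rng):
        pop = pop_with_net([5, 0, 0])
        for _ in range(20):
            assert np.all(select_reproducers(pop, rng) == 0)

    def test_fitness_proportional_frequencies(self, rng):
        pop = pop_with_net([2, 1, 1])
        n = 100_000
        draws = np.concatenate([select_reproducers(pop, rng) for _ in range(n // 3 + 1)])[:n]
        assert abs((draws == 0).mean() - 0.5) < ci99_halfwidth(0.5, n)
        assert abs((draws == 1).mean() - 0.25) < ci99_halfwidth(0.25, n)

    def test_all_zero_payoffs_fall_back_to_uniform(self, rng):
        pop = pop_with_net([0, 0, 0, 0])
        draws = np.concatenate([select_reproducers(pop, rng) for _ in range(5000)])
        freqs = np.bincount(draws, minlength=4) / draws.size
        assert np.all(np.abs(freqs - 0.25) < ci99_halfwidth(0.25, draws.size))


class TestSelectTeacher:
    def test_full_population_sample_returns_maximizer(self, rng):
        pop = pop_with_net([1, 7, 3])
        for _ in range(20):
            assert select_teacher(pop, n_teachers=3, rng=rng) == 1

    def test_ties_broken_uniformly(self, rng):
        pop = pop_with_net([5, 2, 5])
        n = 100_000
        picks = np.array([select_teacher(pop, 3, rng) for _ in range(n)])
        assert not np.any(picks == 1)
        assert abs((picks == 0).mean() - 0.5) < ci99_halfwidth(0.5, n)

    def test_single_prospective_teacher_ignores_payoff(self, rng):
        pop = pop_with_net([0, 100])
        picks = np.array([select_teacher(pop, 1, rng) for _ in range(20_000)])
        assert abs(picks.mean() - 0.5) < ci99_halfwidth(0.5, picks.size)

    def test_oversized_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            select_teacher(pop_with_net([1, 2]), n_teachers=3, rng=rng)


class TestStepIntergenerational:
    def test_asocial_parents_yield_naive_children(self, rng):
        cfg = make_cfg(n_agents=6)
        pop = Population.naive(np.zeros(6, dtype=np.int8), 2)
        run_generation(pop, EnvironmentState(0), cfg, rng)
        child, _ = step_intergenerational(pop, EnvironmentState(0), cfg, rng)
        assert np.all(child.social == 0)
        assert np.all(child.est == 0) and np.all(child.count == 0) and np.all(child.net == 0)

    def test_social_children_inherit_some_parent_estimates(self, rng):
        cfg = make_cfg(n_agents=6, u=0.0, n_teachers=2)
        pop = Population.naive(np.ones(6, dtype=np.int8), 2)
        run_generation(pop, EnvironmentState(0), cfg, rng)
        child, _ = step_intergenerational(pop, EnvironmentState(0), cfg, rng)
        assert np.all(child.social == 1)
        assert np.all((child.count == 0) | (child.count == 1))
        parent_rows = {tuple(r) for r in np.round(pop.est, 12)}
        for row in np.round(child.est, 12):
            assert tuple(row) in parent_rows

    def test_population_size_conserved(self, rng):
        cfg = make_cfg(n_agents=9)
        pop = Population.naive((np.arange(9) % 2).astype(np.int8), 2)
        run_generation(pop, EnvironmentState(0), cfg, rng)
        child, _ = step_intergenerational(pop, EnvironmentState(0), cfg, rng)
        assert child.size == 9

    def test_forced_change_moves_optimum(self, rng):
        cfg = make_cfg(n_agents=4, u=1.0, n_arms=3)
        pop = Population.naive(np.zeros(4, dtype=np.int8), 3)
        run_generation(pop, EnvironmentState(0), cfg, rng)
        env = EnvironmentState(0)
        _, env = step_intergenerational(pop, env, cfg, rng)
        assert env.optimal_arm != 0 and env.changed_this_generation


class TestCheckFixation:
    @pytest.mark.parametrize(
        "traits,expected",
        [([1, 1, 1], SOCIAL_FIXATION), ([0, 0], ASOCIAL_FIXATION), ([1, 0, 1], None)],
    )
    def test_fixation_states(self, traits, expected):
        pop = Population.naive(np.array(traits, dtype=np.int8), 2)
        assert check_fixation(pop) == expected


class TestRunTrial:
    def test_homogeneous_initialization_fixates_immediately(self):
        cfg = make_cfg(n_agents=8)
        r = run_trial(cfg, rng=np.random.default_rng(0), init_social=np.ones(8))
        assert r.outcome == SOCIAL_FIXATION
        assert r.generations == 0

    def test_fixed_seed_is_bit_identical(self):
        cfg = make_cfg(n_agents=20, u=0.2, record_timeseries=True, seed=77)
        r1, r2 = run_trial(cfg), run_trial(cfg)
        assert r1.outcome == r2.outcome
        assert r1.generations == r2.generations
        assert r1.mean_normalized_payoff == r2.mean_normalized_payoff
        assert r1.timeseries.equals(r2.timeseries)

    def test_trial_reaches_fixation_and_payoff_in_unit_interval(self):
        cfg = make_cfg(n_agents=20, u=0.1, max_generations=5000)
        r = run_trial(cfg, rng=np.random.default_rng(3))
        assert r.outcome in (SOCIAL_FIXATION, ASOCIAL_FIXATION)
        assert 0.0 <= r.mean_normalized_payoff <= 1.0

    def test_censoring_at_generation_cap(self):
        # neutral trait, tiny cap: drift cannot fixate N=50 in 2 generations
        cfg = make_cfg(n_agents=50, pi_low=0.9, pi_high=0.9, max_generations=2)
        r = run_trial(cfg, rng=np.random.default_rng(5))
        assert r.outcome == "censored"
        assert r.generations == 2

    def test_timeseries_schema_and_class_means(self):
        cfg = make_cfg(n_agents=30, u=0.2, record_timeseries=True, seed=11)
        r = run_trial(cfg)
        ts = r.timeseries
        assert list(ts.columns) == [
            "generation", "mean_payoff", "mean_payoff_social",
            "mean_payoff_asocial", "n_social", "env_changed",
        ]
        assert len(ts) == r.generations
        assert ts["mean_payoff"].between(0, 1).all()
        assert not ts["env_changed"].iloc[0]  # no shift before the first generation

    def test_trait_heritability_homogeneous_persists(self):
        cfg = make_cfg(n_agents=10, u=0.3, max_generations=50)
        r = run_trial(cfg, rng=np.random.default_rng(9), init_social=np.zeros(10))
        assert r.outcome == ASOCIAL_FIXATION
        assert r.generations == 0
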