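"""SIS simulator: transmission and cost equations, grid design, exact
small-network oracles, conservation, and monotonicity in connectedness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from socage.epi import (
    EpiParams,
    age_fraction,
    control_grid,
    duration_increment,
    enumerate_parameter_grid,
    equilibrium_prevalence,
    estimate_R0,
    infection_cost,
    run_experiment,
    run_sis,
    severity_increment,
    susceptibility_increment,
    transmission_probability,
)

from conftest import make_draw


class TestAgeScaling:
    def test_anchor_values(self):
        assert age_fraction(6) == 0.0
        assert age_fraction(28) == 1.0
        assert age_fraction(17) == pytest.approx(0.5)

    def test_clamped_outside_anchors(self):
        assert age_fraction(3) == 0.0
        assert age_fraction(40) == 1.0

    def test_monotone_non_decreasing(self):
        ages = np.linspace(0, 40, 200)
        f = age_fraction(ages)
        assert np.all(np.diff(f) >= 0)

    def test_realized_increments_at_extremes(self):
        assert duration_increment(6, 10) == 0
        assert duration_increment(28, 10) == 10
        assert severity_increment(28, 2.0) == pytest.approx(2.0)
        assert susceptibility_increment(28, 0.25) == pytest.approx(0.25)

    def test_duration_increment_is_integer(self):
        inc = duration_increment(np.arange(6, 29), 10)
        assert inc.dtype.kind == "i"
        assert np.all(np.diff(inc) >= 0)


class TestTransmissionProbability:
    def test_full_weight_is_baseline(self):
        assert transmission_probability(0.45, 0.0, 1.0) == pytest.approx(0.45)

    def test_zero_weight_is_zero(self):
        assert transmission_probability(0.6, 0.0, 0.0) == 0.0

    def test_sublinear_weight_scaling(self):
        # independently: 0.25**0.7 = exp(0.7 ln 0.25) = 0.37893
        assert transmission_probability(0.45, 0.0, 0.25) == pytest.approx(0.1705, abs=2e-4)

    def test_clamped_at_one(self):
        assert transmission_probability(0.75, 0.25, 8.0) == 1.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            transmission_probability(0.5, 0.0, -0.1)

    @given(
        si=st.floats(0.01, 1.0),
        ai=st.floats(0.0, 0.25),
        w=st.floats(0.0, 50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_always_a_probability(self, si, ai, w):
        p = transmission_probability(si, ai, w)
        assert 0.0 <= p <= 1.0


class TestInfectionCost:
    @pytest.mark.parametrize(
        "args, expected",
        [((5, 0, 1.0, 0.0), 5.0), ((5, 10, 1.0, 2.0), 45.0), ((5, 5, 1.0, 1.0), 20.0)],
    )
    def test_cost_equation(self, args, expected):
        assert infection_cost(*args) == pytest.approx(expected)


class TestParameterGrid:
    def test_24_cells(self):
        assert len(enumerate_parameter_grid()) == 24

    def test_three_controls(self):
        grid = enumerate_parameter_grid()
        assert sum(p.is_control for p in grid) == 3
        assert len(control_grid()) == 3

    def test_each_si_in_eight_cells(self):
        grid = enumerate_parameter_grid()
        for si in (0.45, 0.60, 0.75):
            assert sum(p.si == si for p in grid) == 8

    def test_stable_unique_ids_and_fixed_constants(self):
        grid = enumerate_parameter_grid()
        assert len({p.param_id for p in grid}) == 24
        assert all(p.di == 5 and p.dr == 0 and p.ci == 1.0 for p in grid)
        assert [p.param_id for p in grid] == [p.param_id for p in enumerate_parameter_grid()]


class TestRunSis:
    def test_no_transmission_on_zero_weights(self):
        net = make_draw(np.zeros((5, 5)), ages=(6, 10, 15, 20, 28))
        params = EpiParams(si=0.6, n_initial_infected=1, rng_seed=0)
        res = run_sis(net, params)
        assert res.n_infections.sum() == 1
        assert res.accumulated_cost.sum() == pytest.approx(5.0)  # di * ci
        assert np.sort(res.accumulated_cost)[-2] == 0.0

    def test_isolated_oldest_with_full_immunosenescence_costs_45(self):
        net = make_draw(np.zeros((1, 1)), ages=(28,))
        params = EpiParams(si=0.6, ai_max=0.25, adi_max=10, aci_max=2.0,
                           n_initial_infected=1, rng_seed=1)
        res = run_sis(net, params)
        assert res.infected_steps[0] == 15
        assert res.accumulated_cost[0] == pytest.approx(45.0)

    def test_certain_transmission_infects_neighbour_at_step_one(self, two_node):
        params = EpiParams(si=1.0, n_initial_infected=1, rng_seed=7)
        res = run_sis(two_node(1.0), params, record_events=True)
        first = {}
        for t, i, _ in res.events:
            first.setdefault(i, t)
        assert sorted(first.values()) == [0, 1]

    def test_determinism_and_seed_sensitivity(self, two_node):
        net = two_node(0.3)
        p = EpiParams(si=0.6, n_initial_infected=1, rng_seed=5)
        a, b = run_sis(net, p), run_sis(net, p)
        np.testing.assert_array_equal(a.accumulated_cost, b.accumulated_cost)
        np.testing.assert_array_equal(a.prevalence, b.prevalence)

    def test_prevalence_times_n_is_integer(self):
        rng = np.random.default_rng(3)
        w = rng.gamma(0.5, 0.1, (10, 10))
        w = np.triu(w, 1) + np.triu(w, 1).T
        net = make_draw(w, ages=tuple(rng.integers(6, 29, 10)))
        res = run_sis(net, EpiParams(si=0.6, n_steps=100, rng_seed=2))
        counts = res.prevalence * 10
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)

    def test_empty_network_rejected(self):
        net = make_draw(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            run_sis(net, EpiParams())

    def test_first_infection_time_matches_markov_chain_oracle(self, two_node):
        """2-node chain: the non-seed's first-infection time is geometric(p)
        truncated by the seed's 5-step infectious period (chi-square GoF)."""
        w = 0.25
        p = transmission_probability(0.6, 0.0, w)
        net = two_node(w)
        n_rep = 10_000
        counts = np.zeros(6, dtype=int)  # t = 1..5 or never
        for k in range(n_rep):
            res = run_sis(net, EpiParams(si=0.6, n_initial_infected=1, n_steps=6,
                                         rng_seed=k), record_events=True)
            seed_node = res.events[0][1]
            others = [t for t, i, _ in res.events if i != seed_node]
            first = min(others) if others else None
            counts[first - 1 if first is not None and first <= 5 else 5] += 1
        probs = np.array([(1 - p) ** (t - 1) * p for t in range(1, 6)] + [(1 - p) ** 5])
        chi2 = stats.chisquare(counts, n_rep * probs)
        assert chi2.pvalue > 0.01

    def test_cost_conservation_from_event_log(self):
        rng = np.random.default_rng(9)
        n = 20
        w = rng.gamma(0.5, 0.05, (n, n))
        w = np.triu(w, 1) + np.triu(w, 1).T
        net = make_draw(w, ages=tuple(rng.integers(6, 29, n)))
        params = EpiParams(si=0.75, adi_max=10, aci_max=2.0, n_steps=200, rng_seed=4)
        res = run_sis(net, params, record_events=True)
        # recompute infected steps from the event log, truncating at horizon
        recomputed = np.zeros(n, dtype=int)
        for t, i, dur in res.events:
            recomputed[i] += min(dur, params.n_steps - t)
        np.testing.assert_array_equal(recomputed, res.infected_steps)
        step_cost = 1.0 + severity_increment(np.array(net.ages), 2.0)
        np.testing.assert_allclose(res.accumulated_cost, res.infected_steps * step_cost)
        # state partition: every step's infected count is within [0, n]
        assert np.all((res.prevalence >= 0) & (res.prevalence <= 1))

    def test_expected_cost_non_decreasing_in_strength(self):
        """Star network: leaves ordered by edge weight to the hub accumulate
        ordered expected costs."""
        weights = np.zeros((4, 4))
        for k, w in enumerate((0.02, 0.1, 0.4), start=1):
            weights[0, k] = weights[k, 0] = w
        net = make_draw(weights)
        costs = np.zeros(4)
        for k in range(400):
            res = run_sis(net, EpiParams(si=0.75, n_steps=100,
                                         n_initial_infected=1, rng_seed=k))
            costs += res.accumulated_cost
        assert costs[1] < costs[2] < costs[3]


class TestR0:
    @pytest.mark.parametrize("prev, r0", [(0.5, 2.0), (0.0, 1.0), (2 / 3, 3.0)])
    def test_equilibrium_approximation(self, prev, r0):
        assert estimate_R0(prev) == pytest.approx(r0)

    def test_rejects_prevalence_one(self):
        with pytest.raises(ValueError):
            estimate_R0(1.0)

    def test_equilibrium_window(self, two_node):
        res = run_sis(two_node(0.5), EpiParams(si=0.75, n_steps=300, rng_seed=1))
        prev = equilibrium_prevalence(res, window=100)
        assert prev == pytest.approx(res.prevalence[-100:].mean())


class TestRunExperiment:
    def test_run_count_and_determinism(self, tiny_obs):
        from socage.edges import draw_networks, fit_edge_posterior

        post = fit_edge_posterior(tiny_obs)
        draws = draw_networks(post, 2, rng_seed=0)
        grid = control_grid(n_steps=50)
        res1 = list(run_experiment(draws, grid, master_seed=3))
        res2 = list(run_experiment(draws, grid, master_seed=3))
        assert len(res1) == 2 * 3
        for a, b in zip(res1, res2):
            np.testing.assert_array_equal(a.accumulated_cost, b.accumulated_cost)

    def test_single_pair(self, tiny_obs):
        from socage.edges import draw_networks, fit_edge_posterior

        post = fit_edge_posterior(tiny_obs)
        draws = draw_networks(post, 1, rng_seed=0)
        res = list(run_experiment(draws, [EpiParams(n_steps=20)], master_seed=0))
        assert len(res) == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            list(run_experiment([], control_grid()))
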