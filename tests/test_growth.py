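import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from wheattrade import (CountryPool, GrowthParams, GrowthSchedule,
                        GrowthStallError, TradeNetwork, attempt_edge_event,
                        grow_one_edge, ms_rewire_attempt, rewiring_budget,
                        run_growth, trade_probability)
from wheattrade.errors import ConfigError

from conftest import build_network, random_directed_network


class TestParams:
    def test_validity_bounds(self):
        GrowthParams(1.5, 1.0, 0.01)  # fine
        with pytest.raises(ValueError):
            GrowthParams(2.5, 1.0, 0.01)   # ratio exceeds 1 at z=1
        with pytest.raises(ValueError):
            GrowthParams(0.5, 1.0, 1.5)    # epsilon not a probability
        with pytest.raises(ValueError):
            GrowthParams(-0.1, 1.0, 0.01)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            GrowthSchedule((2000, 2000), (1, 2))
        with pytest.raises(ValueError):
            GrowthSchedule((2000, 2001), (5, 3))
        sched = GrowthSchedule.linear(1986, 1990, 2, 10)
        assert sched.target(1986) == 2 and sched.target(1990) == 10
        with pytest.raises(ConfigError):
            sched.target(1999)


class TestTradeProbability:
    def test_zero_fitness_gives_epsilon(self):
        p = GrowthParams(1.0, 2.0, 0.007)
        assert trade_probability(0.0, 0.0, p) == pytest.approx(0.007)

    def test_beta_zero_epsilon_zero_is_pure_product(self):
        p = GrowthParams(0.9, 0.0, 0.0)
        assert trade_probability(0.5, 0.4, p) == pytest.approx(0.9 * 0.2)

    def test_hand_evaluation(self):
        p = GrowthParams(0.5, 1.0, 0.01)
        assert trade_probability(0.2, 0.3, p) == pytest.approx(0.04 / 1.06)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, deadline=None)
    def test_result_is_probability(self, xi, xj):
        p = GrowthParams(1.5, 1.0, 0.01)
        assert 0.0 <= trade_probability(xi, xj, p) <= 1.0


class TestEdgeEvents:
    def test_epsilon_zero_empty_network_never_fires(self, rng):
        net = TradeNetwork(CountryPool.default(4))
        p = GrowthParams(1.0, 0.5, 0.0)
        assert all(attempt_edge_event(net, p, frozenset(), rng) is None
                   for _ in range(500))

    def test_banned_exporter_never_selected(self, rng):
        net = TradeNetwork(CountryPool.default(3))
        p = GrowthParams(0.5, 0.0, 0.5)
        banned = frozenset({2})
        for _ in range(300):
            edge = attempt_edge_event(net, p, banned, rng)
            if edge is not None:
                assert edge[1] != 2
                net.remove_edge(*edge)

    def test_two_node_pool_only_missing_pair_can_fire(self, rng):
        net = build_network(2, [(0, 1)])
        p = GrowthParams(0.5, 0.0, 0.5)
        fired = set()
        for _ in range(300):
            edge = attempt_edge_event(net, p, frozenset(), rng)
            if edge is not None:
                fired.add(edge)
                net.remove_edge(*edge)
        assert fired == {(1, 0)}

    def test_grow_one_edge_stalls_on_zero_probability(self, rng):
        net = TradeNetwork(CountryPool.default(4))
        p = GrowthParams(1.0, 0.5, 0.0)
        with pytest.raises(GrowthStallError):
            grow_one_edge(net, p, frozenset(), rng, max_attempts=2000)

    def test_grow_one_edge_finds_last_admissible_pair(self, rng):
        n = 3
        edges = [(i, j) for i in range(n) for j in range(n)
                 if i != j and (i, j) != (2, 1)]
        net = build_network(n, edges)
        p = GrowthParams(0.2, 0.1, 0.05)
        assert grow_one_edge(net, p, frozenset(), rng) == (2, 1)

    def test_first_edge_distribution_matches_enumeration(self, rng):
        """Acceptance rates over a fixed 5-node network must follow the
        renormalised per-pair probabilities (uniform draw x acceptance)."""
        net = build_network(5, [(0, 1), (1, 0), (2, 1)])
        p = GrowthParams(1.5, 1.0, 0.05)
        admissible = [(i, j) for i in range(5) for j in range(5)
                      if i != j and not net.has_edge(i, j)]
        weights = np.array([trade_probability(net.fitness(i), net.fitness(j),
                                              p) for i, j in admissible])
        expected = weights / weights.sum()
        counts = {pair: 0 for pair in admissible}
        n_draws = 20_000
        for _ in range(n_draws):
            edge = grow_one_edge(net, p, frozenset(), rng)
            counts[edge] += 1
            net.remove_edge(*edge)
        observed = np.array([counts[pair] for pair in admissible])
        res = stats.chisquare(observed, expected * n_draws)
        assert res.pvalue > 0.01


class TestRewiring:
    def test_budget_expectations(self, rng):
        p = GrowthParams(0.5, 1.0, 0.01, C=100.0, lam=0.01)
        draws0 = [rewiring_budget(0, p, rng) for _ in range(4000)]
        assert np.mean(draws0) == pytest.approx(100.0, rel=0.02)
        draws100 = [rewiring_budget(100, p, rng) for _ in range(4000)]
        assert np.mean(draws100) == pytest.approx(100 * math.exp(-1),
                                                  rel=0.05)
        flat = GrowthParams(0.5, 1.0, 0.01, C=3.0, lam=0.0)
        assert np.mean([rewiring_budget(m, flat, rng)
                        for m in range(2000)]) == pytest.approx(3.0, rel=0.05)

    def test_disjoint_swap_applied(self, rng):
        net = build_network(4, [(0, 1), (2, 3)])
        before = net.total_degree.copy()
        assert ms_rewire_attempt(net, rng)
        assert sorted(net.edges()) == [(0, 3), (2, 1)]
        assert np.array_equal(net.total_degree, before)

    def test_self_loop_swap_rejected(self, rng):
        net = build_network(2, [(0, 1), (1, 0)])
        assert not ms_rewire_attempt(net, rng)
        assert sorted(net.edges()) == [(0, 1), (1, 0)]

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, deadline=None, max_examples=25)
    def test_degrees_conserved_under_rewiring(self, seed):
        rng = np.random.default_rng(seed)
        net = random_directed_network(8, 14, rng)
        in_before = net.in_degree.copy()
        out_before = net.out_degree.copy()
        for _ in range(200):
            ms_rewire_attempt(net, rng)
        assert np.array_equal(net.in_degree, in_before)
        assert np.array_equal(net.out_degree, out_before)


class TestGrowthLoop:
    def test_constant_schedule_adds_nothing(self):
        pool = CountryPool.default(10)
        sched = GrowthSchedule((2000, 2001, 2002), (0, 0, 0))
        res = run_growth(pool, GrowthParams(0.5, 1.0, 0.05), sched, seed=4)
        assert res.network.m == 0
        assert res.series["m"].tolist() == [0.0, 0.0, 0.0]

    def test_m_hits_every_year_target(self):
        pool = CountryPool.default(30)
        sched = GrowthSchedule.linear(2000, 2010, 3, 60)
        res = run_growth(pool, GrowthParams(1.0, 1.0, 0.05, C=10, lam=0.05),
                         sched, seed=5)
        assert res.series["m"].tolist() == [float(e)
                                            for e in sched.cumulative_edges]

    def test_zero_epsilon_closure(self):
        """With epsilon=0 an inactive country can never activate."""
        pool = CountryPool.default(8)
        seed_net = build_network(8, [(0, 1), (1, 0), (2, 0), (0, 2)])
        # only (1,2) and (2,1) are reachable with zero baseline probability
        sched = GrowthSchedule((2000, 2001), (4, 6))
        res = run_growth(pool, GrowthParams(1.5, 1.0, 0.0), sched,
                         seed=6, seed_network=seed_net)
        assert res.network.active_nodes() == {0, 1, 2}

    def test_rewiring_ceases_once_budget_decays(self):
        pool = CountryPool.default(50)
        p = GrowthParams(1.0, 1.0, 0.05, C=5.0, lam=0.2)
        # by m=100 the expected budget is 5e-9: no swap should ever trigger
        sched = GrowthSchedule.linear(2000, 2005, 100, 160)
        seed_rng = np.random.default_rng(7)
        seed_net = random_directed_network(50, 100, seed_rng)
        res = run_growth(pool, p, sched, seed=8, seed_network=seed_net)
        # degrees of the seed edges can only change through growth, not
        # swaps: every seed edge must still be present
        for edge in seed_net.edges():
            assert res.network.has_edge(*edge)

    def test_reproducible_under_seed(self):
        pool = CountryPool.default(20)
        sched = GrowthSchedule.linear(2000, 2005, 2, 30)
        p = GrowthParams(1.0, 1.0, 0.05, C=8, lam=0.1)
        a = run_growth(pool, p, sched, seed=9)
        b = run_growth(pool, p, sched, seed=9)
        assert sorted(a.network.edges()) == sorted(b.network.edges())
        assert a.series.equals(b.series)
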