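import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wheattrade import (BanRegistry, CountryPool, GrowthParams,
                        GrowthSchedule, ShockSchedule, ShockSpec,
                        apply_export_ban, run_growth, run_shock_experiment,
                        select_targets_attack, select_targets_error,
                        shock_delta)
from wheattrade.errors import ConfigError

from conftest import build_network


class TestSpecsAndSchedule:
    def test_spec_validation(self):
        with pytest.raises(ConfigError):
            ShockSpec("tsunami", 3, 1, 2017)
        with pytest.raises(ConfigError):
            ShockSpec("attack", 0, 1, 2017)
        with pytest.raises(ConfigError):
            ShockSpec("attack", 3, 1, 2017, mode="alphabetical")

    def test_gap_rule(self):
        ShockSchedule((ShockSpec("attack", 3, 1, 2017),
                       ShockSpec("error", 3, 1, 2020)))
        with pytest.raises(ConfigError):
            ShockSchedule((ShockSpec("attack", 3, 5, 2017),
                           ShockSpec("error", 3, 1, 2020)))

    def test_ban_registry_expiry(self):
        reg = BanRegistry()
        reg.ban(7, until_year=2019)     # banned 2017, duration 2
        assert 7 in reg.active(2017) and 7 in reg.active(2018)
        assert 7 not in reg.active(2019)
        reg.ban(7, until_year=2018)     # re-ban never shortens
        assert 7 in reg.active(2018)
        reg.expire(2020)
        assert 7 not in reg


class TestErrorTargeting:
    def test_all_exporters_when_k_equals_pool(self, rng):
        net = build_network(5, [(0, 1), (0, 2), (3, 2)])
        assert set(select_targets_error(net, 2, rng)) == {1, 2}
        single = build_network(3, [(0, 1)])
        assert select_targets_error(single, 1, rng) == [1]

    def test_shortfall_error(self, rng):
        net = build_network(5, [(0, 1)])
        with pytest.raises(ConfigError):
            select_targets_error(net, 2, rng)

    def test_selection_uniform_over_exporters(self, rng):
        net = build_network(8, [(0, k) for k in range(1, 7)])
        counts = np.zeros(8)
        n_draws = 6000
        for _ in range(n_draws):
            counts[select_targets_error(net, 1, rng)[0]] += 1
        res = stats.chisquare(counts[1:7])
        assert res.pvalue > 0.01
        assert counts[0] == counts[7] == 0


class TestAttackTargeting:
    def test_top_k_by_total_degree(self, rng):
        # degrees: 0 -> 5, 1 -> 3, 2 -> 2, 3 -> 1 (+ helpers)
        net = build_network(8, [(0, 1), (0, 2), (1, 0), (2, 0), (3, 0),
                                (1, 4)])
        top2 = select_targets_attack(net, 2, "total_degree",
                                     "simultaneous", rng)
        assert top2 == [0, 1]

    # A (node 0, total degree 5) exports only to B (node 1); B and C
    # (node 2) tie at total degree 3.  Removing A's out-edges demotes B
    # to 2, so a re-ranking second pick must be C, while a one-shot
    # ranking breaks the B/C tie at random.
    RANK_SHIFT_EDGES = [(0, 4), (0, 5), (0, 6), (0, 7), (1, 0),
                        (1, 8), (1, 9),
                        (2, 10), (2, 11), (2, 4)]

    def test_sequential_differs_when_removal_shifts_ranking(self):
        seq_picks = set()
        sim_picks = set()
        for s in range(30):
            net = build_network(12, self.RANK_SHIFT_EDGES)
            sim = select_targets_attack(net, 2, "total_degree",
                                        "simultaneous",
                                        np.random.default_rng(s))
            seq = select_targets_attack(net, 2, "total_degree",
                                        "sequential",
                                        np.random.default_rng(s))
            assert sim[0] == seq[0] == 0
            sim_picks.add(sim[1])
            seq_picks.add(seq[1])
        assert seq_picks == {2}
        assert sim_picks == {1, 2}

    def test_tie_at_rank_k_randomized(self):
        net = build_network(6, [(1, 0), (1, 3), (4, 2), (5, 2)])
        # nodes 1 and 2 tie with total degree 2 at the top
        picks = {select_targets_attack(
            net, 1, "total_degree", "simultaneous",
            np.random.default_rng(s))[0] for s in range(30)}
        assert picks == {1, 2}


class TestBans:
    def test_hub_out_edges_removed_imports_kept(self):
        net = build_network(6, [(k, 0) for k in range(1, 5)] + [(0, 5)])
        reg = BanRegistry()
        removed = apply_export_ban(net, [0], duration=1, year=2017,
                                   registry=reg)
        assert removed == 4
        assert net.out_degree[0] == 0 and net.in_degree[0] == 1
        assert 0 in reg.active(2017) and 0 not in reg.active(2018)

    def test_banning_all_exporters_empties_network(self):
        net = build_network(4, [(0, 1), (2, 1), (0, 3)])
        reg = BanRegistry()
        apply_export_ban(net, [1, 3], duration=1, year=2000, registry=reg)
        assert net.m == 0

    def test_double_ban_idempotent_and_extending(self):
        net = build_network(3, [(0, 1)])
        reg = BanRegistry()
        apply_export_ban(net, [1], 1, 2000, reg)
        apply_export_ban(net, [1], 5, 2000, reg)
        assert net.m == 0
        assert 1 in reg.active(2004)


class TestDeltaAccounting:
    def test_hand_computed_difference(self):
        series = pd.DataFrame({"year": [2000, 2001, 2002],
                               "n_nodes": [10.0, 12.0, 15.0],
                               "apl": [2.0, 2.5, 2.2]})
        delta = shock_delta(series, [2002])
        assert list(delta.index) == [2002]
        assert delta.loc[2002, "n_nodes"] == pytest.approx(3.0)
        assert delta.loc[2002, "apl"] == pytest.approx(-0.3)

    def test_missing_year_rejected(self):
        series = pd.DataFrame({"year": [2000, 2002], "n_nodes": [1.0, 2.0]})
        with pytest.raises(ConfigError):
            shock_delta(series, [2001])


class TestExperimentLoop:
    def test_empty_scenario_arms_identical(self):
        pool = CountryPool.default(40)
        sched = GrowthSchedule.linear(2000, 2006, 3, 60)
        params = GrowthParams(1.0, 1.0, 0.05, C=10, lam=0.05)
        res = run_shock_experiment([params, params], None, sched, pool,
                                   seed=11, record="fit")
        for sf, uf in zip(res.shocked_series, res.unshocked_series):
            assert sf.equals(uf)

    def test_shock_run_bans_and_shapes(self):
        pool = CountryPool.default(40)
        sched = GrowthSchedule.linear(2000, 2010, 3, 80)
        params = GrowthParams(1.0, 1.0, 0.05, C=10, lam=0.05)
        scenario = ShockSchedule((ShockSpec("attack", 2, 2, 2005),))
        res = run_shock_experiment([params], scenario, sched, pool,
                                   seed=12, record="fit")
        log = res.shock_logs[0][0]
        assert log["year"] == 2005 and log["edges_removed"] >= 0
        assert set(res.arm_summary["arm"]) == {"shocked", "unshocked"}
        # one row per (year x arm x metric)
        n_metrics = res.arm_summary["metric"].nunique()
        assert len(res.arm_summary) == 2 * len(sched.years) * n_metrics
        assert res.delta_mean is not None and list(res.delta_mean.index) == \
            [2005]

    def test_banned_exporters_gain_no_out_edges_during_ban(self):
        pool = CountryPool.default(30)
        sched = GrowthSchedule.linear(2000, 2008, 3, 70)
        params = GrowthParams(1.0, 1.0, 0.08, C=0, lam=0)
        scenario = ShockSchedule((ShockSpec("attack", 2, 3, 2003),))
        result = run_growth(pool, params, sched, scenario, seed=13)
        targets = result.shock_log[0]["targets"]
        # out-degree at the end of the final ban year must still be zero:
        # removal emptied it and bans covered 2003-2005
        by_year = result.series.set_index("year")
        # rerun year by year is costly; instead assert via a fresh run that
        # records the network at the last ban year
        partial = GrowthSchedule(tuple(y for y in sched.years if y <= 2005),
                                 tuple(e for y, e in sched
                                       if y <= 2005))
        res2 = run_growth(pool, params, partial, scenario, seed=13)
        assert res2.shock_log[0]["targets"] == targets
        assert all(res2.network.out_degree[t] == 0 for t in targets)
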