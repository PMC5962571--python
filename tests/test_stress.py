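"""Osmostress scheduling semantics, distances, and repression fitting."""

import numpy as np
import pandas as pd
import pytest

from cyclefish import (
    GeneParams,
    StressConfig,
    apply_stress_schedule,
    default_td_grid,
    distribution_distance,
    grid_search_td,
    simulate_stress_population,
)
from cyclefish.estimation import PhaseDistributions
from cyclefish.simulate import _spawn_seeds
from cyclefish.stress import (
    _CoupledGeneSampler,
    _simulate_stress_gene,
    tables_to_distributions,
)


class TestApplyStressSchedule:
    def test_zero_duration_is_identity(self, model):
        g = model.gene("CLN2")
        a = apply_stress_schedule(g, 30.0, 0.0, horizon=250.0)
        b = apply_stress_schedule(g, 30.0, 0.0, horizon=250.0)
        assert not a.rate_modified and a.shift == 0.0
        assert np.array_equal(a.bounds, b.bounds)

    def test_interrupted_window_resumes_with_remaining_duration(self):
        # window on cycle [20, 40); onset at cycle 30 (absolute 45) with
        # 10 min remaining; t_d = 12: high resumes at absolute 57 for 10 min
        g = GeneParams("X", 5.0, 0.5, 0.1, ((20.0, 40.0),))
        sched = apply_stress_schedule(g, 30.0, 12.0, horizon=200.0)
        t_s = 15.0 + 30.0
        assert sched.t_onset == t_s
        assert sched.rate_at(t_s - 0.1) == 5.0  # still in window pre-stress
        assert sched.rate_at(t_s + 6.0) == 0.5  # repressed
        assert sched.rate_at(t_s + 12.0 + 5.0) == 5.0  # resumed
        assert sched.rate_at(t_s + 12.0 + 10.1) == 0.5  # remaining spent
        assert sched.shift == pytest.approx(12.0)

    def test_window_inside_repression_defers_whole(self):
        g = GeneParams("X", 5.0, 0.5, 0.1, ((20.0, 25.0),))
        # window at absolute [35, 40); onset cycle 18 -> t_s=33, t_d=10
        sched = apply_stress_schedule(g, 18.0, 10.0, horizon=200.0)
        assert sched.rate_at(36.0) == 0.5
        assert sched.rate_at(43.5) == 5.0  # deferred to [43, 48)
        assert sched.shift == pytest.approx(43.0 - 35.0)

    @pytest.mark.parametrize("onset", [0.0, 25.0, 35.0, 100.0, 118.0, 128.5])
    @pytest.mark.parametrize("t_d", [5.0, 12.0, 28.0])
    def test_high_exposure_conserved(self, model, onset, t_d):
        # numeric integration oracle over a horizon ending in the long low
        # stretch of both schedules (no window straddles the end)
        g = model.gene("CLN2")
        H = 90.0 + 15.0 + 129.0
        grid = np.arange(0.0, H, 0.01) + 0.005
        r0 = apply_stress_schedule(g, onset, 0.0, horizon=H).rate_at(grid)
        r1 = apply_stress_schedule(g, onset, t_d, horizon=H).rate_at(grid)
        assert (r0 == g.k_high).sum() == (r1 == g.k_high).sum()
        assert np.isclose(r0.sum() * 0.01, r1.sum() * 0.01, rtol=1e-9)

    def test_negative_duration_rejected(self, model):
        with pytest.raises(ValueError):
            apply_stress_schedule(model.gene("CLN2"), 10.0, -1.0)


class TestDistributionDistance:
    def _nested(self, hists):
        return {
            t: {g: PhaseDistributions(gene=g, hist=h) for g, h in per_gene.items()}
            for t, per_gene in hists.items()
        }

    def test_identical_inputs_give_zero(self):
        d = self._nested({0.0: {"A": {"S": {1: 4, 3: 2}, "G2": {0: 7}}}})
        assert distribution_distance(d, d) == 0.0

    def test_disjoint_single_bins_give_two_per_group(self):
        a = self._nested({0.0: {"A": {"S": {1: 10}, "G2": {5: 3}}}})
        b = self._nested({0.0: {"A": {"S": {2: 10}, "G2": {9: 3}}}})
        assert distribution_distance(a, b) == pytest.approx(4.0)  # 2 groups x 2

    def test_matches_brute_force_double_loop(self, rng):
        def random_hists():
            out = {}
            for t in (0.0, 15.0):
                out[t] = {}
                for g in ("A", "B"):
                    out[t][g] = {
                        ph: {int(c): int(n) for c, n in
                             zip(rng.integers(0, 40, 5), rng.integers(1, 20, 5))}
                        for ph in ("eG1", "S", "T/C")
                    }
            return out

        ha, hb = random_hists(), random_hists()
        a, b = self._nested(ha), self._nested(hb)

        total = 0.0
        from cyclefish.phases import PHASE_NAMES
        for t in ha:
            for g in ha[t]:
                for ph in PHASE_NAMES:
                    fa, fb = np.zeros(32), np.zeros(32)
                    for c, n in ha[t][g].get(ph, {}).items():
                        fa[min(c, 31)] += n
                    for c, n in hb[t][g].get(ph, {}).items():
                        fb[min(c, 31)] += n
                    if fa.sum():
                        fa /= fa.sum()
                    if fb.sum():
                        fb /= fb.sum()
                    for i in range(32):
                        total += (fa[i] - fb[i]) ** 2
        assert distribution_distance(a, b) == pytest.approx(total, rel=1e-12)

    def test_mismatched_keys_rejected(self):
        a = self._nested({0.0: {"A": {"S": {1: 1}}}})
        b = self._nested({15.0: {"A": {"S": {1: 1}}}})
        with pytest.raises(ValueError, match="sampling times"):
            distribution_distance(a, b)
        c = self._nested({0.0: {"B": {"S": {1: 1}}}})
        with pytest.raises(ValueError, match="genes"):
            distribution_distance(a, c)


class TestSimulateStressPopulation:
    def test_deterministic_per_seed(self, model):
        cfg = StressConfig(t_d={"CLN2": 10.0}, sampling_times=(0.0, 15.0))
        a = simulate_stress_population(model, cfg, n_cells=30, seed=5)
        b = simulate_stress_population(model, cfg, n_cells=30, seed=5)
        for t in a:
            assert a[t].equals(b[t])

    def test_unstressed_limit_matches_cycle_statistics(self, model):
        # all t_d = 0: every sampling time is an ordinary asynchronous
        # population; per-gene means must match the periodic-state means
        from cyclefish.model import periodic_mean_at

        cfg = StressConfig(t_d={}, sampling_times=(0.0, 30.0))
        tables = simulate_stress_population(model, cfg, n_cells=1500, seed=8)
        u = np.linspace(0, 129, 5000)
        for t, df in tables.items():
            for g in model.genes:
                exp_mean = periodic_mean_at(g, u).mean()
                x = df[df["gene"] == g.name]["count"]
                se = x.std(ddof=1) / np.sqrt(len(x))
                assert abs(x.mean() - exp_mean) < 4 * se + 0.05

    def test_cyclins_dip_then_recover_sic1_stable(self, model):
        cfg = StressConfig(t_d={"CLN2": 28.0, "CLB5": 12.0})
        tables = simulate_stress_population(model, cfg, n_cells=1200, seed=13)
        mean = {
            t: df.groupby("gene")["count"].mean() for t, df in tables.items()
        }
        assert mean[15.0]["CLN2"] < 0.5 * mean[0.0]["CLN2"]
        assert mean[90.0]["CLN2"] > 0.7 * mean[0.0]["CLN2"]
        assert abs(mean[15.0]["SIC1"] - mean[0.0]["SIC1"]) < 0.2 * mean[0.0]["SIC1"]

    def test_too_short_simulation_budget_rejected(self, model):
        cfg = StressConfig(t_d={}, total_sim_minutes=100.0)
        with pytest.raises(ValueError, match="too short"):
            simulate_stress_population(model, cfg, n_cells=2, seed=0)


class TestCoupledSamplerAgreesWithSSA:
    def test_same_law_as_gillespie(self, model, rng):
        # dual route: the birth/lifetime representation and the SSA must
        # produce the same count distribution under a stressed schedule
        g = model.gene("CLB5")
        n = 4000
        onsets = rng.uniform(0, 129, n)
        n0 = rng.poisson(g.basal_mean, n)
        seeds_a = _spawn_seeds(101, n)
        seeds_b = _spawn_seeds(202, n)
        times = np.array([0.0, 15.0, 45.0])
        ssa, _ = _simulate_stress_gene(g, 12.0, onsets, n0, seeds_a, times, 129.0)
        sampler = _CoupledGeneSampler(g, onsets, n0, seeds_b, 129.0, 46.0)
        coupled, _ = sampler.counts(12.0, times)
        from scipy.stats import chi2_contingency

        for k in range(len(times)):
            hi = max(ssa[:, k].max(), coupled[:, k].max())
            ha = np.bincount(ssa[:, k], minlength=hi + 1)
            hb = np.bincount(coupled[:, k], minlength=hi + 1)
            keep = (ha + hb) >= 10
            tab = np.array([np.append(ha[keep], ha[~keep].sum()),
                            np.append(hb[keep], hb[~keep].sum())])
            tab = tab[:, tab.sum(axis=0) > 0]
            p = chi2_contingency(tab).pvalue
            assert p > 0.001, f"t={times[k]}: p={p}"


@pytest.fixture(scope="module")
def small_obs(model):
    cfg = StressConfig(t_d={"CLN2": 28.0, "CLB5": 12.0})
    return simulate_stress_population(model, cfg, n_cells=600, seed=31)


class TestGridSearch:
    def test_default_grid_is_5_to_30(self):
        assert np.array_equal(default_td_grid(), np.arange(5, 31))

    def test_single_point_grid_returns_it(self, model, small_obs):
        res = grid_search_td(
            small_obs, model, {"CLN2": [28], "CLB5": [12]}, n_sims=40, seed=1
        )
        assert res.best == {"CLN2": 28.0, "CLB5": 12.0}
        assert len(res.surface) == 1

    def test_argmin_stable_across_seeds(self, model, small_obs):
        g = {"CLN2": np.arange(20, 37), "CLB5": np.arange(5, 21)}
        r1 = grid_search_td(small_obs, model, g, n_sims=200, seed=2)
        r2 = grid_search_td(small_obs, model, g, n_sims=200, seed=12)
        for gene in ("CLN2", "CLB5"):
            assert abs(r1.best[gene] - r2.best[gene]) <= 2

    def test_deterministic_surface(self, model, small_obs):
        g = {"CLN2": [26, 28], "CLB5": [10, 12]}
        r1 = grid_search_td(small_obs, model, g, n_sims=50, seed=3)
        r2 = grid_search_td(small_obs, model, g, n_sims=50, seed=3)
        pd.testing.assert_frame_equal(r1.surface, r2.surface)

    def test_array_distance_consistent_with_public_distance(self, model):
        # the vectorized frequency arrays used inside the grid search must
        # reproduce distribution_distance exactly on the same tables
        from cyclefish.stress import _obs_freq_array

        cfg_a = StressConfig(t_d={"CLN2": 28.0, "CLB5": 12.0})
        cfg_b = StressConfig(t_d={})
        ta = simulate_stress_population(model, cfg_a, n_cells=150, seed=41)
        tb = simulate_stress_population(model, cfg_b, n_cells=150, seed=42)
        na = tables_to_distributions(ta, model.gene_names)
        nb = tables_to_distributions(tb, model.gene_names)
        times = sorted(na)
        fa = _obs_freq_array(na, model.gene_names, times, model.phase_map)
        fb = _obs_freq_array(nb, model.gene_names, times, model.phase_map)
        assert ((fa - fb) ** 2).sum() == pytest.approx(
            distribution_distance(na, nb), rel=1e-12
        )

    def test_empty_grid_rejected(self, model, small_obs):
        with pytest.raises(ValueError):
            grid_search_td(small_obs, model, {"CLN2": []}, n_sims=10, seed=0)
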