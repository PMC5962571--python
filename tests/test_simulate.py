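"""Exactness and statistics of the Gillespie population simulator."""

import numpy as np
import pytest
from scipy import stats

from cyclefish import (
    GeneParams,
    ModelSpec,
    SnapshotMatrix,
    mean_trajectory,
    per_cell_temporal_cv,
    phase_binned_counts,
    phase_count_distribution,
    population_noise_timecourse,
    simulate_cell,
    simulate_population,
)
from cyclefish.simulate import ANAPHASE_SHIFT, _run_gene_ssa, _spawn_seeds


def _chi2_pvalue(samples, pmf_func, lam_hint):
    """Goodness of fit of integer samples against a discrete law."""
    kmax = max(int(np.quantile(samples, 0.999)), int(lam_hint * 2) + 5)
    obs = np.bincount(np.minimum(samples, kmax), minlength=kmax + 1)
    exp = pmf_func(np.arange(kmax + 1))
    exp[-1] = 1.0 - exp[:-1].sum()
    keep = exp * len(samples) >= 5
    obs_k = np.append(obs[keep], obs[~keep].sum())
    exp_k = np.append(exp[keep], exp[~keep].sum()) * len(samples)
    return stats.chisquare(obs_k, exp_k).pvalue


class TestExactness:
    def test_pure_death_monotone_to_zero(self):
        bounds = np.array([0.0, 60.0])
        rates = np.array([0.0])
        snap = np.arange(61.0)
        counts = _run_gene_ssa(bounds, rates, 0.5, 5, snap, seed=7)
        assert counts[0] == 5
        assert (np.diff(counts) <= 0).all()
        assert counts[-1] == 0

    def test_stationary_law_is_poisson(self):
        # constant-rate birth-death started at its stationary Poisson law
        k, p, n = 5.0, 0.5, 20_000
        lam = k / p
        rng = np.random.default_rng(3)
        seeds = _spawn_seeds(99, n)
        bounds, rates = np.array([0.0, 30.0]), np.array([k])
        final = np.array(
            [
                _run_gene_ssa(bounds, rates, p, int(n0), np.array([30.0]), int(s))[0]
                for n0, s in zip(rng.poisson(lam, n), seeds)
            ]
        )
        assert _chi2_pvalue(final, lambda x: stats.poisson.pmf(x, lam), lam) > 0.001

    def test_ensemble_mean_tracks_cme_mean(self, model):
        # mean over cells at every minute vs the closed-form ODE solution
        # from the Poisson(k_low/p) initial condition at anaphase
        n = 1000
        snap = simulate_population(model, n, seed=5)
        t_cycle = snap.times + (129.0 - ANAPHASE_SHIFT)
        frac_ok = []
        for j, gname in enumerate(snap.genes):
            g = model.gene(gname)
            theory = mean_trajectory(
                g, t_cycle, m0=g.basal_mean, t0=t_cycle[0]
            )
            mean = snap.counts[:, :, j].mean(axis=0)
            se = snap.counts[:, :, j].std(axis=0, ddof=1) / np.sqrt(n)
            z = np.abs(mean - theory) / np.maximum(se, 1e-9)
            frac_ok.append((z <= 3).mean())
            assert (z <= 5).all()
        assert np.mean(frac_ok) >= 0.97  # pointwise 3-SE band, 435 comparisons

    def test_variance_matches_poisson_law(self, model):
        # counts are Poisson at every instant, so variance tracks the mean
        snap = simulate_population(model, 1500, seed=6)
        for j in range(len(snap.genes)):
            mean = snap.counts[:, :, j].mean(axis=0)
            var = snap.counts[:, :, j].var(axis=0, ddof=1)
            sel = mean > 2.0
            ratio = var[sel] / mean[sel]
            assert np.median(np.abs(ratio - 1)) < 0.1
            assert (np.abs(ratio - 1) < 0.35).mean() > 0.95


class TestReproducibility:
    def test_bitwise_reproducible(self, model):
        a = simulate_population(model, 20, seed=11)
        b = simulate_population(model, 20, seed=11)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_population(model, 20, seed=12)
        assert not np.array_equal(a.counts, c.counts)

    def test_single_cell_population_composes(self, model):
        pop = simulate_population(model, 1, seed=21)
        seed0 = int(_spawn_seeds(21, 1)[0])
        cell = simulate_cell(
            model, 129.0 - ANAPHASE_SHIFT, ANAPHASE_SHIFT + 129.0, seed0, pop.times
        )
        assert np.array_equal(pop.counts[0], cell)

    def test_phase_binning_deterministic(self, model, pmap):
        snap = simulate_population(model, 50, seed=4)
        t1 = phase_binned_counts(snap, pmap, seed=9)
        t2 = phase_binned_counts(snap, pmap, seed=9)
        assert t1.equals(t2)


class TestNoiseStatistics:
    def _snap(self, counts):
        counts = np.asarray(counts)
        return SnapshotMatrix(
            times=np.arange(counts.shape[1], dtype=float),
            counts=counts,
            genes=["G"] * counts.shape[2],
            sim_origin=0.0,
            cycle_length=float(counts.shape[1]),
            seed=0,
        )

    def test_identical_cells_have_zero_cv(self):
        counts = np.tile(np.arange(1, 11)[None, :, None], (5, 1, 1))
        cv = population_noise_timecourse(self._snap(counts))
        assert np.allclose(cv, 0.0)

    def test_matches_naive_two_pass_oracle(self, model):
        snap = simulate_population(model, 100, seed=8)
        cv = population_noise_timecourse(snap)
        for j in range(3):
            for t in (0, 60, 144):
                x = snap.counts[:, t, j].astype(float)
                expected = (
                    np.sqrt(((x - x.mean()) ** 2).sum() / (len(x) - 1)) / x.mean()
                    if x.mean() > 0
                    else np.nan
                )
                assert cv[t, j] == pytest.approx(expected, rel=1e-12) or (
                    np.isnan(cv[t, j]) and np.isnan(expected)
                )

    def test_zero_mean_minutes_are_nan_not_error(self):
        counts = np.zeros((4, 6, 1), dtype=int)
        counts[:, 3:, 0] = 2
        cv = population_noise_timecourse(self._snap(counts))
        assert np.isnan(cv[0, 0]) and cv[3, 0] == 0.0

    def test_temporal_cv_constant_trajectory_is_zero(self):
        counts = np.full((3, 10, 2), 7)
        assert np.allclose(per_cell_temporal_cv(counts), 0.0)

    def test_temporal_cv_of_deterministic_mean_matches_quadrature(self, model):
        # feed the closed-form mean trajectory itself as one 'cell'
        g = model.gene("SIC1")
        minutes = np.arange(129.0)
        m = mean_trajectory(g, minutes, m0=2.0)
        cv = per_cell_temporal_cv(m[None, :, None])[0, 0]
        fine = mean_trajectory(g, np.linspace(0, 129, 20001)[:-1], m0=2.0)
        oracle = fine.std() / fine.mean()
        assert cv == pytest.approx(oracle, rel=0.03)


class TestPhaseBinnedCounts:
    def test_histograms_match_analytic_phase_distributions(self, pmap):
        # in silico smFISH sampling of SSA trajectories vs the closed-form
        # Poisson-mixture law (independent oracle).  Binned counts are read
        # at integer minutes (floor of the sampled time), so the oracle
        # mixes Poisson(m(minute)) with weights equal to each minute's
        # overlap with the phase interval.
        from cyclefish.model import periodic_mean_at

        gene = GeneParams("SIC1", 22.15, 1.72, 0.56, ((118.09, 124.05),))
        model1 = ModelSpec(genes=(gene,), phase_map=pmap)
        snap = simulate_population(model1, 12_000, seed=17)
        cells = phase_binned_counts(snap, pmap, seed=18)
        for phase in ("T/C", "S", "Ana"):
            a, b = pmap.phase_interval(phase)
            minutes = np.arange(int(np.floor(a)), int(np.ceil(b)))
            weights = np.clip(np.minimum(minutes + 1, b) - np.maximum(minutes, a),
                              0, None)
            weights /= weights.sum()
            means = periodic_mean_at(gene, minutes.astype(float))
            sup = np.arange(201)
            pmf = np.zeros(201)
            for w, m in zip(weights, means):
                pmf += w * stats.poisson.pmf(sup, m)
            pmf[-1] += 1.0 - pmf.sum()
            x = cells[cells["phase"] == phase]["count"].to_numpy()
            lam = pmf @ sup
            pval = _chi2_pvalue(x, lambda c: pmf[c], lam)
            assert pval > 0.001, f"phase {phase}: p={pval}"

    def test_minute_binned_means_approach_continuous_law(self, pmap):
        # the minute-resolution read is within one minute's drift of the
        # continuous phase mixture (coarse sanity on the same data)
        gene = GeneParams("SIC1", 22.15, 1.72, 0.56, ((118.09, 124.05),))
        model1 = ModelSpec(genes=(gene,), phase_map=pmap)
        snap = simulate_population(model1, 4000, seed=27)
        cells = phase_binned_counts(snap, pmap, seed=28)
        for phase in ("S", "G2"):
            pmf = phase_count_distribution(gene, pmap, phase, n_max=200)
            x = cells[cells["phase"] == phase]["count"]
            assert x.mean() == pytest.approx(pmf @ np.arange(201), abs=0.5)

    def test_phase_occupancy_proportional_to_duration(self, model, pmap):
        snap = simulate_population(model, 4000, seed=19)
        cells = phase_binned_counts(snap, pmap, seed=20)
        occ = cells[cells["gene"] == "SIC1"]["phase"].value_counts(normalize=True)
        for name, frac in zip(pmap.phase_names, pmap.fractions):
            se = np.sqrt(frac * (1 - frac) / 4000)
            assert abs(occ.get(name, 0.0) - frac) < 4 * se
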