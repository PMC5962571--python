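"""The synthetic data generator as a faithful data-generating process."""

import numpy as np
import pytest
from scipy import stats

from cyclefish import (
    GeneParams,
    ModelSpec,
    StressConfig,
    SynthConfig,
    generate_cell_table,
    generate_spot_table,
    generate_stress_experiment,
    quantify_cells,
)
from cyclefish.model import periodic_mean_at
from cyclefish.phases import PHASE_NAMES


class TestGenerateCellTable:
    def test_homogeneous_gene_counts_are_poisson(self, pmap):
        g = GeneParams("X", 2.0, 2.0, 0.4, ())
        spec = ModelSpec(genes=(g,), phase_map=pmap)
        tab = generate_cell_table(SynthConfig(model=spec, n_cells=20_000, seed=4))
        x = tab["count"].to_numpy()
        lam = 5.0
        kmax = 16
        obs = np.bincount(np.minimum(x, kmax), minlength=kmax + 1)
        exp = stats.poisson.pmf(np.arange(kmax + 1), lam)
        exp[-1] = 1 - exp[:-1].sum()
        assert stats.chisquare(obs, exp * len(x)).pvalue > 0.001

    def test_phase_means_match_analytic_oracle(self, model, pmap):
        tab = generate_cell_table(SynthConfig(model=model, n_cells=5000, seed=6))
        u = np.linspace(0, 129, 20001)[:-1]
        for g in model.genes:
            for ph in ("lG1", "T/C", "G2"):
                a, b = pmap.phase_interval(ph)
                m_exp = periodic_mean_at(g, u[(u >= a) & (u < b)]).mean()
                x = tab.query("gene == @g.name and phase == @ph")["count"]
                se = x.std(ddof=1) / np.sqrt(len(x))
                assert abs(x.mean() - m_exp) <= 3.5 * se + 0.02

    def test_seed_deterministic(self, model):
        cfg = SynthConfig(model=model, n_cells=100, seed=9)
        assert generate_cell_table(cfg).equals(generate_cell_table(cfg))

    def test_fast_and_ssa_paths_statistically_indistinguishable(self, pmap):
        # two-sample chi-square on pooled counts, per phase group
        gene = GeneParams("SIC1", 22.15, 1.72, 0.56, ((118.09, 124.05),))
        spec = ModelSpec(genes=(gene,), phase_map=pmap)
        n = 20_000
        fast = generate_cell_table(
            SynthConfig(model=spec, n_cells=n, seed=14), method="analytic"
        )
        ssa = generate_cell_table(
            SynthConfig(model=spec, n_cells=n, seed=15), method="ssa"
        )
        for ph in ("Ana", "T/C", "eG1"):
            a = fast[fast["phase"] == ph]["count"].to_numpy()
            b = ssa[ssa["phase"] == ph]["count"].to_numpy()
            hi = max(a.max(), b.max())
            ha = np.bincount(a, minlength=hi + 1)
            hb = np.bincount(b, minlength=hi + 1)
            keep = (ha + hb) >= 10
            tab = np.array([np.append(ha[keep], ha[~keep].sum()),
                            np.append(hb[keep], hb[~keep].sum())])
            tab = tab[:, tab.sum(axis=0) > 0]
            assert stats.chi2_contingency(tab).pvalue > 0.001, ph


class TestSpotRoundTrip:
    def test_noiseless_round_trip_is_identity(self, model):
        cfg = SynthConfig(model=model, n_cells=400, intensity_sigma=0.0, seed=2)
        cells = generate_cell_table(cfg)
        spots = generate_spot_table(cells, cfg)
        quant = quantify_cells(spots)
        merged = cells.merge(
            quant, on=["cell_id", "gene"], suffixes=("_true", "_est")
        )
        assert (merged["count_true"] == merged["count_est"]).all()
        assert (merged["ts_true"] == merged["ts_est"]).all()
        # zero-count cells emit no spots and are absent from the spot table
        zeros = cells[cells["count"] == 0]
        spot_cells = set(zip(spots["cell_id"], spots["gene"]))
        assert all(
            (c, g) not in spot_cells
            for c, g in zip(zeros["cell_id"], zeros["gene"])
        )

    def test_noisy_round_trip_accuracy(self, model):
        # Monte-Carlo oracle at the default noise level: the vast majority
        # of cells come back within one molecule of the truth
        cfg = SynthConfig(model=model, n_cells=1200, intensity_sigma=0.25, seed=3)
        cells = generate_cell_table(cfg)
        quant = quantify_cells(generate_spot_table(cells, cfg))
        merged = cells.merge(
            quant, on=["cell_id", "gene"], how="left", suffixes=("_true", "_est")
        )
        merged["count_est"] = merged["count_est"].fillna(0)
        err = (merged["count_true"] - merged["count_est"]).abs()
        assert (err <= 1).mean() >= 0.90
        assert (err == 0).mean() >= 0.70


class TestStressExperimentFixture:
    def test_unstressed_tables_all_match_baseline(self, model):
        cfg = SynthConfig(model=model, n_cells=800, seed=5)
        tables = generate_stress_experiment(cfg, StressConfig(t_d={}))
        baseline = tables[0.0].groupby("gene")["count"].mean()
        for t, df in tables.items():
            m = df.groupby("gene")["count"].mean()
            for g in model.gene_names:
                assert m[g] == pytest.approx(baseline[g], rel=0.25, abs=0.4)

    def test_repression_depletes_cyclins_at_15_min(self, model):
        cfg = SynthConfig(model=model, n_cells=800, seed=5)
        tables = generate_stress_experiment(
            cfg, StressConfig(t_d={"CLN2": 28.0, "CLB5": 12.0})
        )
        m0 = tables[0.0].groupby("gene")["count"].mean()
        m15 = tables[15.0].groupby("gene")["count"].mean()
        assert m15["CLN2"] < 0.5 * m0["CLN2"]

    def test_seed_deterministic(self, model):
        cfg = SynthConfig(model=model, n_cells=50, seed=7)
        sc = StressConfig(t_d={"CLN2": 10.0})
        a = generate_stress_experiment(cfg, sc)
        b = generate_stress_experiment(cfg, sc)
        for t in a:
            assert a[t].equals(b[t])

    def test_emits_all_default_sampling_times(self, model):
        cfg = SynthConfig(model=model, n_cells=20, seed=1)
        tables = generate_stress_experiment(cfg, StressConfig(t_d={}))
        assert sorted(tables) == [0.0, 15.0, 30.0, 45.0, 60.0, 90.0]
        assert set(tables[0.0].columns) >= {"cell_id", "phase", "gene", "count"}
        assert set(tables[0.0]["phase"]).issubset(PHASE_NAMES)


class TestConfigValidation:
    def test_bad_configs_rejected(self, model):
        with pytest.raises(ValueError):
            SynthConfig(model=model, n_cells=0)
        with pytest.raises(ValueError):
            SynthConfig(model=model, intensity_sigma=-0.1)
        with pytest.raises(ValueError):
            StressConfig(t_d={"CLN2": -3.0})
        with pytest.raises(ValueError):
            StressConfig(sampling_times=(15.0, 0.0))
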