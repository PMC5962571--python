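# cyclefish

Cell-cycle-resolved analysis of single-cell mRNA counts in budding yeast —
in silico synchronization, stochastic transcription modelling, analytic
maximum-likelihood fitting, and osmostress repression fitting for the G1/S
regulators *SIC1*, *CLN2* and *CLB5*.

## The problem

Single-molecule FISH counts mRNAs in fixed cells, so it delivers exact
copy numbers but no time axis. If each cell can be assigned a cell-cycle
phase from morphological markers, the population becomes its own clock:
the fraction of cells in a phase estimates the fraction of the cycle spent
there, and phase-resolved count distributions become time-resolved data —
*in silico synchronization*. `cyclefish` implements that reconstruction
and the modelling built on it, for experimentalists and modellers working
with phase-annotated smFISH (or equivalent) count data.

## The model

Each gene is an independent birth–death process on a 129-min cycle
partitioned into 7 phases (eG1, lG1, S, G2, P/M, Ana, T/C):

    transcription:  ∅ → mRNA   at rate k(t)
    degradation:    mRNA → ∅   at rate p·N

where k(t) switches between a high rate k_high inside one or two
deterministic high-expression windows of the cycle and a basal k_low > 0
outside. The system is linear, so with Poisson initial conditions the
chemical master equation solves in closed form: the count is Poisson with
mean m(t) obeying dm/dt = k(t) − p·m. A cell observed in a phase is
uniformly distributed within it, so each phase's count distribution is a
uniform Poisson mixture — the likelihood used to fit (k_high, k_low, p)
and the window times per gene, with one- vs two-window models compared by
AIC = 2k − 2 ln L. Populations are also simulated exactly (Gillespie SSA)
for noise time-courses (CV = sd/mean), and osmotic stress is modelled as a
per-gene repression of duration t_d that forces k(t) to k_low and defers
interrupted windows, fitted by grid search over 676 integer (t_d,CLN2,
t_d,CLB5) combinations against phase- and time-resolved distributions.

## Worked example

```python
import numpy as np
from cyclefish import (
    SynthConfig, PhaseDistributions, default_phase_map, fit_gene,
    generate_cell_table, promoter_activity, table1_model,
)

model = table1_model()          # shipped kinetic constants
pmap = default_phase_map()      # 7 phases on the 129-min cycle

print({g.name: round(promoter_activity(g), 2) for g in model.genes})
# {'SIC1': 7.77, 'CLN2': 0.45, 'CLB5': 15.08}   # basal activity, % of peak

# synthesize a 2000-cell smFISH-style experiment and refit SIC1
table = generate_cell_table(SynthConfig(model=model, n_cells=2000, seed=1))
data = PhaseDistributions.from_cell_table(table, "SIC1")
fit = fit_gene(data, pmap, n_windows=1, seed=7)
g = fit.params
print(f"k_high={g.k_high:.2f} k_low={g.k_low:.2f} p={g.p:.3f} "
      f"window={tuple(round(x, 1) for x in g.windows[0])}")
# k_high=20.48 k_low=1.48 p=0.486 window=(118.4, 123.7)
```

The generating values were k_high = 22.15 min⁻¹, k_low = 1.72 min⁻¹,
p = 0.56 min⁻¹ with the high-expression window at 118.09–124.05 min: from
2000 fixed cells the fitter recovers the rates to within ~10–15% (median
error across replicate datasets is ~5%) and the window boundaries to
within half a minute — static snapshots carry the kinetic information once
phases supply the clock.

## Analysis scripts

`analysis/` holds the numbered pipeline, each a thin driver over the
library writing to `results/`:

1. `01_phase_map.py` — occupancy counts → phase durations (the time axis)
2. `02_cycle_simulation.py` — 2000-cell SSA time-courses, noise (CV), and
   phase-binned distributions vs the analytic solution
3. `03_fit_kinetics.py` — ML refits of SIC1 and CLN2 (1 vs 2 windows, AIC)
4. `04_spot_quantification.py` — spot-intensity normalization round trip,
   TS calling, per-phase summaries
5. `05_stress_gridsearch.py` — synthetic osmostress experiment and
   recovery of the repression durations (28, 12) min by grid search

A `cyclefish` CLI exposes the same steps (`simulate`, `synth`, `quantify`,
`summarize`, `fit`, `stress-fit`, `phase-map`).

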