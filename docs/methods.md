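# Methods

`cyclefish` analyses cell-cycle-resolved single-cell mRNA counts of the
budding-yeast G1/S regulators *SIC1*, *CLN2* and *CLB5*: it reconstructs
temporal expression dynamics from a snapshot of an asynchronous population
(in silico synchronization), fits a stochastic transcription model to the
phase-resolved count distributions, and fits the durations of
osmostress-induced transcriptional repression. This note records the model,
its assumptions, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## The cell-cycle clock

The cycle of length *t* = 129 min is partitioned into seven phases in fixed
order — early G1, late G1, S, G2, prometa-/metaphase (P/M), anaphase (Ana),
telophase/cytokinesis (T/C) — with half-open intervals `[start, end)` and
times reduced modulo 129. Phase durations are estimated from occupancy:
a phase's duration is the cycle length times the fraction of an
asynchronous population observed in that phase. This assumes cells are
uniformly distributed in time; the exponential age structure of a growing
population (young cells slightly over-represented) is deliberately not
modelled, which biases durations of late phases upward by at most a few
percent — well below the sampling noise of ~2000-cell experiments.

Default occupancy fractions are eG1 0.211, lG1 0.180, S 0.180, G2 0.166,
P/M 0.147, Ana 0.086, T/C 0.030. The eG1, G2 and T/C values are measured
unstressed occupancies; the remaining four are package defaults chosen so
that anaphase plus T/C spans ~15 min, consistent with simulations starting
at anaphase 15 min before cycle start. All are configurable
(`build_phase_map`, `phase-map` CLI).

## Transcription model

Each gene is an independent birth-death process:

    dN: birth at rate k(t), death at rate p * N

with `k(t) = k_high` inside one or two deterministic high-expression
windows of the cycle and `k_low > 0` (basal) outside, and first-order
degradation `p` constant over the cycle. Deterministic window switching —
rather than a stochastic two-state (telegraph) promoter — is the model's
central simplification: the data to fit are phase-resolved population
histograms, which constrain the time course of the mean rate but not the
promoter's switching statistics.

Shipped constants (`data/table1.yaml`), rates in min⁻¹, windows in cycle
minutes:

| gene | k_high | k_low | p    | windows                        |
|------|--------|-------|------|--------------------------------|
| SIC1 | 22.15  | 1.72  | 0.56 | 118.09–124.05                  |
| CLN2 | 4.4    | 0.02  | 0.09 | 20.57–39.83, 119.01–124.05     |
| CLB5 | 3.05   | 0.46  | 0.51 | 40.16–62.59, 120.26–124.35     |

The relative promoter activity `100 * k_low / k_high` evaluates to 7.8%
(SIC1), 0.45% (CLN2) and 15.1% (CLB5) from these constants.

### Analytic solution

The system is linear (monomolecular), so with a Poisson initial condition
the copy number stays Poisson for all time, with mean obeying
`dm/dt = k(t) − p m`, solved piecewise:
`m(t) = k/p + (m0 − k/p) exp(−p Δt)` on each constant-rate segment. Phase
distributions are evaluated at the cycle-periodic steady state: over one
cycle the mean map is affine, `m(T) = A + e^{−pT} m(0)`, whose fixed point
`A / (1 − e^{−pT})` every trajectory approaches geometrically. Using the
periodic solution makes likelihoods independent of an arbitrary simulation
start.

A cell observed in a phase sits at an unknown, uniformly distributed time
within it, so the phase's count distribution is the uniform mixture of
`Poisson(m(t))` over the phase interval, computed by midpoint quadrature at
0.1-min resolution (the mean is piecewise-exponential and smooth; the
quadrature error is orders of magnitude below sampling noise). Pmfs are
truncated at n_max = 200 with tail mass folded into the last bin; plausible
counts stay below ~40.

## Gillespie simulation

Populations are simulated exactly with the stochastic simulation algorithm.
Rates are piecewise constant, so standard Gillespie applies within each
segment; a tentative event that crosses a window boundary is discarded and
re-drawn from the boundary — exact by memorylessness. Each cell starts at
anaphase (cycle time 114 = 129 − 15) with independent `Poisson(k_low/p)`
initial counts — for the shipped constants this coincides with the periodic
state at anaphase to three decimals, because every gene's last window ends
> 5 mean lifetimes before anaphase. Runs last 15 + 129 min with snapshots
at every integer minute; cycle time is `(114 + t) mod 129`. Per-cell RNG
streams derive from one master seed via a counter-based scheme
(`SeedSequence`), so results are bitwise reproducible and independent of
iteration order. The event loop is JIT-compiled (numba); 2000 cells over a
full cycle take well under a second.

Noise statistics follow the conventions: population noise is CV(t) =
sd/mean across cells per minute (sample sd, n−1); per-cell temporal CV is
taken across one cell's 129 per-minute values; minutes (or cells) with zero
mean report NaN rather than raising.

`phase_binned_counts` mimics fixed-cell smFISH sampling in reverse: each
simulated cell is assigned one uniform random cycle time (phases hit
proportionally to duration) and contributes its counts at that minute.

## Maximum-likelihood estimation

Genes are fitted independently (their dynamics are statistically
independent given the schedule). The log-likelihood of phase-resolved
histograms is the histogram-weighted log of the analytic phase-mixture
pmfs at the periodic state; pmf values are floored at 1e-300 to guard
`log(0)` for counts far in the tail.

The optimizer is cyclic coordinate descent with a line search per
coordinate, multi-started from 20 Latin-hypercube draws within bounds.
Parameterization: log rates (k_high, k_low, p, bounds 1e-4..100 min⁻¹) and
each window as (center ∈ [0, 129), width ∈ [1, 60] min), which keeps
windows positive and lets them wrap the cycle boundary (wrapped windows are
split in two). Numerical choices, each made after the plain variant proved
inadequate on synthetic data:

- **Line search**: a 16-point bracket scan of the coordinate's full range
  followed by golden-section refinement inside the best bracket. Likelihood
  slices are multimodal in window position; an unbracketed golden section
  over the whole box converges to the wrong basin.
- **Pattern move**: after each coordinate sweep, a line search along the
  sweep's net displacement (Hooke-Jeeves acceleration) jumps down the
  correlated k_high/k_low/p ridge that coordinate steps alone crawl along.
- **Coarse-to-fine quadrature with multi-candidate polish**: restarts
  explore on a 0.5-min mixture grid (≈3× cheaper per evaluation); the five
  best candidates are polished at 0.1 min and the overall winner returned.
  Polishing more than one matters: the coarse ranking can misorder nearby
  window-placement basins whose likelihoods differ by ~1 unit.
- **Convergence**: a sweep that improves the log-likelihood by less than
  `max(1e-8 · |loglik|, 1e-3)` terminates the descent (cap 200 sweeps).
  The absolute floor matters: near the optimum, coordinate descent
  zig-zags along the correlated k_high/k_low/p ridge in steps of ~5e-4
  log-likelihood units per sweep indefinitely — far below any
  statistically meaningful difference (AIC-relevant differences are ≥ 2).

One- and two-window models (5 and 7 free parameters) are compared by
AIC = 2k − 2 ln L; ties prefer the smaller model. When the fitted high and
low rates differ by < 5%, window placement is unidentifiable; the fit is
flagged and reported with a single window. On 2000-cell synthetic data the
fitter recovers SIC1's k_high and p with median errors of ~5–9% across
replicate datasets (each fit's likelihood at least matches the generating
parameters') and CLN2's two windows to ≲ 0.5 min, with AIC preferring two
windows by ~4500 units.

## Osmostress model

Hyperosmotic shock hits each cell at a uniformly random cycle position.
For an affected gene (the cyclins; SIC1 is unaffected), transcription is
forced to `k_low` for a repression period `t_d` — basal transcription
persists under stress, so repression is not a hard zero. Any un-executed
portion of a high window overlapping the repression resumes at its end with
the remaining duration preserved, and all later windows shift by the same
deferral, conserving total scheduled high-expression time; the cell's phase
clock pauses for the longest deferral across affected genes (so mRNA peaks
stay aligned with the delayed phase labels). These deferral rules are this
package's explicit convention; alternative delay strategies are selectable
on the schedule level. Populations are sampled 0/15/30/45/60/90 min after
each cell's own onset.

### Repression-duration fitting

`grid_search_td` scores every combination of integer repression durations
(default 5–30 min per cyclin: 676 combinations) by the total squared
distance between model and observed mRNA distributions, summed over genes,
the seven phases, the six sampling times, and count bins 0–30 plus a >30
tail (relative frequencies within each gene × phase × time group). The
surface and its argmin are returned.

The default evaluator is **analytic**: given a cell's onset and the
stressed schedule, its count at a sampling time is exactly Poisson with the
closed-form mean, so each group's distribution is an exact finite mixture
over that group's onsets and the surface carries no Monte-Carlo noise. Two
stochastic alternatives are kept for cross-checking (`method="simulation"`
with an exact coupled birth-death sampler, and the SSA in
`simulate_stress_population`); all three agree in law, and the test suite
verifies it. The choice is not cosmetic: with 200 cells per combination the
plug-in Monte-Carlo distance is both noisy (argmin scatter ±4–6 min across
seeds) and biased toward short repressions, because its expectation adds a
sampling-variance term `Σ f(1−f)/n` that grows with the dispersion of the
distributions; a debiased simulation distance (subtracting that term's
unbiased estimate, available via `debias=True`) removes the bias but not
the noise. Onsets are stratified over the cycle (one uniform draw per
equal-width stratum — the marginal law is unchanged, but the
onset-position component of the noise vanishes), and all combinations
share onsets and RNG streams, so per-gene results are cached per candidate
duration. With the analytic evaluator, recovery of generating durations
(28, 12) min from a 2000-cell synthetic experiment is within ±1 min across
observation and search seeds.

## Spot quantification

Spot intensities are normalized by the median intensity of the gene's spot
population; molecules per spot are the rounded ratio
(round-half-away-from-zero, floored at one molecule — upstream detection is
assumed to have removed sub-threshold noise, and whether sub-median spots
should instead be discarded is an open convention). Nuclear spots with ≥ 3
molecules are transcription sites; cytoplasmic spots never are. Per-phase
summaries report mean, median, SEM, CV (sample sd over mean) and expressing
/ TS-positive fractions.

## Synthetic data

The generator emulates the data-generating process the analysis assumes:

- **Cell tables**: uniform random cycle times; counts either drawn from the
  analytic periodic-state Poisson law (fast path) or read from SSA
  trajectories (both paths are statistically indistinguishable; verified by
  two-sample chi-square at n = 20 000). Default population size 2000 cells,
  matching the simulated experiments throughout.
- **Spot tables**: every mRNA becomes a single-molecule cytoplasmic spot;
  a transcription site aggregates 3 + Poisson(1) molecules (capped by the
  cell's count) into one nuclear spot. Intensity noise is lognormal with
  unit median and sigma = 0.25 — unit median makes median normalization
  exactly self-consistent, and sigma = 0.25 reproduces the regime where
  ~90% of spots are called single-molecule. TS flags follow a synthetic
  convention (probability proportional to the instantaneous transcription
  rate, requiring ≥ 3 transcripts), so TS-positive fractions peak in each
  gene's high-expression phases.
- **Stress experiments**: `simulate_stress_population` wrapped to emit the
  observed-data CSV dialect at the six sampling times.

What passing tests show: the estimators recover the parameters of data
generated by the model itself, at realistic sample sizes and noise levels.
What they do not show: robustness to features of real smFISH data the
generator omits — segmentation and spot-detection errors, cell-to-cell
extrinsic rate variability, mother/daughter asymmetry, phase
misclassification, and partial mRNA export/localization effects.

## Known limitations

- Degradation is one constant per gene; regulated decay (e.g. cell-cycle-
  dependent destabilization) would be absorbed into the window estimates.
- The repression deferral rules and the phase-clock pause are conventions;
  distinguishing them from alternatives (no delay; fixed delay) needs
  time-resolved single-cell data rather than fixed-cell snapshots.
- Fits report point estimates only; no confidence intervals.
- The cycle length is fixed at its population doubling-time estimate;
  cell-to-cell period variability is not modelled.
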