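# Published kinetic parameterization of cell-cycle-regulated transcription
# for the three G1/S regulators.  Rates in molecules/min (k) and 1/min (p);
# high-expression windows [t_start, t_end) in cycle minutes on a 129-min cycle.
cycle_length: 129.0
genes:
  - name: SIC1
    k_high: 22.15
    k_low: 1.72
    p: 0.56
    windows:
      - [118.09, 124.05]
  - name: CLN2
    k_high: 4.4
    k_low: 0.02
    p: 0.09
    windows:
      - [20.57, 39.83]
      - [119.01, 124.05]
  - name: CLB5
    k_high: 3.05
    k_low: 0.46
    p: 0.51
    windows:
      - [40.16, 62.59]
      - [120.26, 124.35]
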