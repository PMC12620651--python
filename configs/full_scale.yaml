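# Full-scale validation experiment: baseline scenario.
#
# One file = one scenario.  The published design crosses this baseline with:
#   n_founders: 250 / 500 / 750 / 1000
#   mean_dd:    0 / 0.5 / 1 / 2 / 4   paired with h2_trait 0.6 / 0.3 / 0.3 / 0.3 / 0.1
#   n_crosses:  400 (baseline B) plus B + N/2, B + N, B + 2N
# Edit the three keys below (or generate variants) to sweep the grid.
# A single 40-cycle run with per-cycle model fits takes on the order of hours
# on one CPU; use `crosskit simulate --config ... --seed S`.

n_founders: 250
n_chromosomes: 18
sites_per_chr: 5400
markers_per_chr: 1000   # 18 000 SNP panel in total
n_qtl: 56
mean_dd: 2.0
var_dd: 0.2
h2_trait: 0.3
burn_in_cycles: 10
n_cycles: 40
n_crosses: 400
progeny_per_cross: 1
stage_h2: [0.15, 0.25, 0.45, 0.65]
stage_reps: [1, 2, 3, 3]
stage_advance: [0.90, 0.80, 0.70, 0.60]
map_length: 1.0
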