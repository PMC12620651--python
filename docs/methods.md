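# Methods

## Model and estimation

crosskit fits, per trait,

    y = X β + f b + Z a + W d* + e

on phenotype *means*: replicate records are averaged per genotype ×
factor cell before fitting, and genotyped-only individuals are retained
(dropped records are counted in the log). `X` is treatment-coded with an
intercept; aliased columns are removed by pivoted QR.

**Codings.** Dosages count a fixed allele (ALT in VCF, the second listed
allele in HapMap); all predictions are invariant to this choice after
re-estimation, which the test suite asserts. The heterozygosity code for
dosage `k` at ploidy `ρ` is `k(ρ−k)/C(ρ,2)` — the fraction of the
within-individual allele pairs that are heterozygous (0/1 for diploids,
e.g. 2/3 for a duplex tetraploid). The genomic inbreeding coefficient is
`f = 1 − mean(W row)`, i.e. mean homozygosity: it needs no reference panel,
is exactly conserved with the W coding, and makes `f b` a pure function of
W. Both Z and W are centred on the training-panel mean; the centring
vectors are stored so candidate parents are scored on the same scale.

**Scaling.** Marker-effect priors use `s_a = Σ_i 2 p̄_i q̄_i (ρ/2)` and
`s_d = Σ_i (2 p̄_i q̄_i)²` with `p̄_i` the panel mean frequency, so σ²_a and
σ²_d are on the phenotypic scale; any fixed convention would do, and the
choice is pinned by a duality test against the relationship-matrix (GBLUP)
form. Classical (0/1-heterozygote) dominance coding is used, as literally
defined above, not the natural-and-orthogonal parameterisation.

**REML.** Variance components (additive, dominance deviation, optional
extra iid factors, residual) are estimated on the observation-level
covariance `V = Σ_k σ²_k G_k + σ²_e I`. Each iteration proposes an
average-information (AI) Newton step and falls back to the EM update
`σ²_k ← σ²_k + σ⁴_k (y'P G_k P y − tr(P G_k))/n` whenever the AI step
leaves the parameter space or would decrease the restricted likelihood, so
the recorded log-likelihood trace is non-decreasing by construction.
Defaults: variance floor 1e-8, relative log-likelihood tolerance 1e-6,
maximum 200 iterations; non-convergence returns a flagged fit with a
warning rather than raising. If `f` is numerically constant (e.g. a fully
homozygous panel) the slope `b` is aliased with the intercept and dropped
with a warning.

**Marker effects.** In the ridge parameterisation the BLUPs back-solve as
`â = (σ²_a/s_a) Z' P y` and `d̂* = (σ²_d/s_d) W' P y`; the individual-level
GBLUP and this form are equivalent (tested to 1e-6). The per-marker
dominance effect consumed by cross prediction is `d_i = d*_i − b/m`: under
the mean-homozygosity definition of `f`, one unit of heterozygosity at one
of `m` markers changes `f` by `−1/m`, so the directional term contributes
`−b/m` per marker (positive under inbreeding depression, `b < 0`). Users
who want the deviation-only effects can read `dominance_deviation`
directly.

**Multi-trait indices** are handled by fitting each trait independently and
combining per-trait cross merits with the selection-index weights. This
matches the runGPCP-style interface without requiring multivariate REML;
whether an index should instead be formed before fitting is a genuinely
open design point, and the per-trait route was chosen for transparency of
the per-trait variance components.

## Cross prediction

All `n(n−1)/2` unordered candidate pairs (plus selfs only on request —
target species are clonal outcrossers) are scored with the closed-form F1
mean; scoring is vectorised as a rank-one expansion and blocked over pairs
so peak memory is O(block × m), which keeps >50 000-combination candidate
sets tractable. Ties are broken lexicographically by (Parent1, Parent2)
with the smaller ID stored first, so output is a deterministic total
order. For diploids the formula equals exhaustive gamete enumeration
(tested to 1e-10 over random cases); for polyploids it is applied unchanged
to `dosage/ploidy` frequencies without any claim of equivalence to
polysomic progeny enumeration — a documented limitation. Merits are on the
centred model scale (no intercept), so they compare within, not across,
runs. Sex codes (1 male, 2 female, 3/4 monoecious) exclude male×male and
female×female pairs; absent codes are unconstrained.

## Simulator

The simulator is deliberately minimal but end-to-end faithful: each cycle's
model fits go through the same `genio`/`dirdom_model`/`cross_predict` code
path as real-data analyses.

* **Founders.** Independent sites with U-shaped Beta(0.5, 0.5) allele
  frequencies (clipped to [0.02, 0.98]); linkage disequilibrium is built by
  the 10 random-mating burn-in generations rather than by a coalescent
  founder model. This is a simplification: founder LD and demographic
  structure of real panels are not emulated, so passing tests speak to the
  selection dynamics, not to LD-dependent prediction accuracy in any
  specific crop.
* **Trait.** Biallelic QTL (default 56 genome-wide, disjoint from the SNP
  panel) with additive effects rescaled so founder additive variance is 1
  and mean 0; dominance effects `d_i = |a_i| δ_i`, `δ_i ~ N(meanDD, varDD)`
  with `varDD = 0.2` by default (configurable; only the mean dominance
  degree is varied across published scenarios). Genotypic value:
  `Σ a_i (dosage−1) + d_i · 1{het}`.
* **Meiosis.** Poisson crossovers on a 1-Morgan map per chromosome, no
  interference; tetraploid meiosis is out of scope.
* **Pipeline.** CE → PYT → AYT → UYT with h² 0.15/0.25/0.45/0.65, reps
  1/2/3/3, advancement 90/80/70/60 % by phenotype rank (floor with an
  epsilon guard: 1000 entrants → 900 → 720 → 504 → 302). Plot error
  variances are fixed from the *founder* genetic variance, so phenotyping
  precision does not artificially improve as selection erodes variance.
  Training data for the cycle's model are all phenotyped individuals, each
  contributing its replication-weighted mean across the stages it reached;
  only UYT survivors are candidate parents.
* **Selection arms.** GEBV: additive-only fit, top `2·n_crosses/k` parents
  (k = 2 by default) chain-mated round-robin. GPCP: full
  directional-dominance fit, top `n_crosses` pairs by predicted F1 mean.
  Both arms produce identical progeny counts and descend from a
  bit-identical post-burn-in population (per-arm RNG streams are spawned
  from one seed). Because the burn-in is shared, burn-in ΔUC is
  identically zero; burn-in neutrality is additionally checked through
  heterozygosity retention under random mating.
* **Tracking.** UC = mean(g) + i·sd(g) over the progeny of the selected
  crosses, with the selected fraction taken at the cross level
  (n_crosses / candidate pairs) unless overridden; H is the mean
  heterozygote frequency over the SNP panel. ΔUC and ΔH are GPCP − GEBV.
* **Replication.** Trajectories are reported per seed; multi-seed runs
  (≥ 3 recommended — single-replicate trends are noisy) are exposed via
  `--seeds`.

**Scale.** Tests and the acceptance script run a reduced design — 100
founders, 2 chromosomes, 500 SNPs, 56 QTL, 20 crosses × 5 progeny, 10
burn-in + 10 selection cycles, 5 seeds — chosen as the smallest
configuration where the dominance-vs-additive heterozygosity contrast is
resolvable over seed noise. The full design (N = 250–1000, 18
chromosomes, 40 cycles) ships as `configs/full_scale.yaml` and runs as a
long job. At reduced scale the purely additive trait can show *negative*
late-cycle ΔH (cross-selection concentrates on the best parents when merits
are midparent-additive); at full scale the published expectation is ΔH > 0
in all scenarios, largest at low dominance — this full-scale behaviour is
not asserted at desk scale.

## Fixtures

Fixture genotypes draw a per-individual baseline inbreeding level
`F_j ~ U(0, 0.5)` (calls homozygous with probability `F_j`, Hardy–Weinberg
otherwise), emulating the genomic-inbreeding spread of clonal germplasm
panels. This matters: with iid binomial dosages `f` is nearly constant
across individuals and the slope `b` is unidentifiable at any realistic
sample size. Even with this spread, `b` is weakly identified — `f` lies in
the column span of W, so the GLS standard error of `b̂` is ≈ 2.3 per
replicate at n = 500, m = 1000 — hence recovery of `b` is assessed as
unbiasedness within Monte-Carlo error while variance components are held
to ±30 % on 20-replicate means. Every fixture writes a truth sidecar
(effects, components, scalings) so test oracles never re-simulate.

## Numerical conventions and edge cases

* Missing genotype calls: W and f use observed calls only; model fitting
  requires a complete matrix, produced by `filter_and_impute` (marker-mean
  imputation after MAF/missingness QC). Imputation beyond marker-mean fill
  is out of scope.
* HapMap polyploid heterozygotes: single-letter IUPAC codes cannot encode
  partial polyploid dosage and are rejected rather than guessed; explicit
  allele strings of length ρ are accepted.
* Marker positions are metadata only; no genetic map enters the model.
* Degenerate designs: monomorphic panels raise (zero additive scaling);
  empty phenotype/genotype joins raise; variance components pinned at the
  1e-8 floor are logged.
* Determinism: all randomness flows from explicit seeds
  (`numpy.random.Generator` / `SeedSequence`); repeated seeded runs produce
  byte-identical outputs, recorded with input checksums in each run
  manifest.
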