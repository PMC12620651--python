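# crosskit

Genomic prediction of **cross performance** for breeding programmes, with a
forward simulator to compare cross-based parent selection against classical
GEBV truncation.

In clonally propagated outcrossers (yam, cassava, potato, ...) inbreeding
depression and heterosis make the *pair* of parents matter, not just each
parent's additive merit. crosskit fits a genomic mixed model with additive
and directional-dominance marker effects, back-solves per-marker effects,
and scores every candidate parental combination with a closed-form
prediction of the F1 family's mean genotypic value.

## The model

Phenotype means are modelled as

```
y = X β + f b + Z a + W d* + e
```

where `X β` are fixed effects, `f` is each individual's genomic inbreeding
coefficient (mean homozygosity across markers) with slope `b` — the
directional-dominance term capturing inbreeding depression (`b < 0`) or
heterosis — `Z` holds mean-centred allele dosages (0..ploidy; diploid,
tetraploid and hexaploid panels are supported), `W` holds mean-centred
heterozygosity codes (for dosage `k` at ploidy `ρ`, the fraction
`k(ρ−k)/C(ρ,2)` of heterozygous allele pairs), and
`a ~ N(0, I σ²_a/s_a)`, `d* ~ N(0, I σ²_d/s_d)`, `e ~ N(0, I σ²_e)` with
VanRaden-style scalings `s_a`, `s_d`. Variance components are estimated by
EM-REML with average-information acceleration.

A cross between parents with within-parent allele frequencies `p_i` and
`p'_i` (`q_i = 1 − p_i`, `y_i = p_i − p'_i`) is scored by the predicted F1
mean

```
M_F1 = Σ_i [ a_i (p_i − q_i − y_i) + d_i (2 p_i q_i + y_i (p_i − q_i)) ]
```

with `d_i = d*_i − b/m` folding the directional term into per-marker
dominance effects. For diploids this equals exhaustive gamete enumeration;
it is symmetric in the parents and reduces to the midparent additive score
when `d ≡ 0`. Multi-trait merit is a selection-index weighted sum. The
GEBV baseline is the usual sum of centred dosages times additive effects.

The `breeding_sim` module replays the validation design: founder
populations, traits with configurable mean dominance degree, a
random-mating burn-in, a four-stage clonal pipeline
(CE → PYT → AYT → UYT with h² = 0.15/0.25/0.45/0.65, reps 1/2/3/3,
advancement 90/80/70/60 %), and per-cycle tracking of the usefulness
criterion `UC = mean(g) + i·sd(g)` and mean heterozygosity for a GEBV arm
and a GPCP (cross-performance) arm.

## Worked example

Generate a seeded fixture panel (30 genotypes × 80 SNPs, phenotypes
simulated from the model above) and rank crosses:

```bash
crosskit fixtures --n 30 --markers 80 --seed 13 --out demo
crosskit predict --pheno demo/fixture_pheno.csv --geno demo/fixture.vcf \
    --traits trait --weights 1 --ncrosses 5 --min-maf 0 --max-missing 1 \
    --out demo/pred
```

The run logs the fitted variance components, then writes `demo/pred/crosses.csv`:

```
ID,Parent1,Parent2,merit
1,g000,g004,0.612149923442185
2,g005,g014,0.5603543924871555
3,g000,g009,0.5434680124710864
4,g006,g009,0.5312397071985533
5,g009,g017,0.5272085438663943
```

`ID` is the 1-based rank; `merit` is the index-weighted predicted F1 mean on
the centred model scale (compare within a run, not across runs). With a
sexes CSV (`--sexes`), codes 1 = male, 2 = female, 3/4 = monoecious are
reported and incompatible pairs (male×male, female×female) are dropped.
Every output directory gets a `manifest.json` (inputs, checksums, seed,
version) for reproducibility.

A two-trait yam-style call mirrors the usual selection-index setup:

```bash
crosskit predict --pheno pheno.csv --geno geno.vcf \
    --traits Yield,DMC --weights 3,1 --ploidy 2 --ncrosses 150 --out out/
```

Simulations run from a YAML scenario:

```bash
crosskit simulate --config configs/full_scale.yaml --seed 1 --out sim_out
```

`configs/full_scale.yaml` is the full 40-cycle experiment (N = 250,
18 chromosomes, 18 000 SNPs); expect hours on one CPU. Reduced-scale
configs (see `tests/conftest.py`) run in seconds.

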