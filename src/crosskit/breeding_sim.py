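"""Forward-in-time clonal breeding-programme simulator.

Validates cross-performance selection against GEBV truncation selection in a
recurrent clonal pipeline.  Each simulated cycle sends a progeny cohort
through four field-trial stages — clonal evaluation (CE), preliminary yield
trial (PYT), advanced yield trial (AYT) and uniform yield trial (UYT) — with
rising heritability (0.15 / 0.25 / 0.45 / 0.65), rising replication
(1 / 2 / 3 / 3) and fixed advancement fractions (90 / 80 / 70 / 60 %).  The
UYT survivors are the candidate parent set.  The GEBV arm ranks candidates on
additive marker effects and chain-mates the top parents; the GPCP arm ranks
all candidate pairs on the predicted F1 mean (additive + directional
dominance model) and mates the top pairs.  Both arms produce identical
progeny counts and start from a bit-identical post-burn-in population.

Genomes are diploid: binary haplotype pairs per chromosome, crossovers
Poisson with a 1-Morgan map and no interference.  Founder allele frequencies
follow a U-shaped Beta(0.5, 0.5) spectrum with independent sites; the random
mating burn-in generations then build linkage structure.  Traits are
controlled by biallelic QTL with additive effects rescaled so founder
additive variance is 1 (mean 0) and dominance effects ``d_i = |a_i| delta_i``
with dominance degree ``delta_i ~ N(mean_dd, var_dd)``.

Progress is tracked per cycle and arm as the usefulness criterion
``UC = mean(g) + i sd(g)`` over the selected crosses' progeny (``i`` the
standardized selection intensity at the cross level) and panel mean
heterozygosity H, plus the contrasts dUC = UC_gpcp - UC_gebv and
dH = H_gpcp - H_gebv.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import dirdom_model as dm
from . import cross_predict as cp
from .genio import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "Population",
    "simulate_founders",
    "meiosis",
    "phenotype",
    "run_stage_pipeline",
    "select_and_mate",
    "usefulness_criterion",
    "selection_intensity",
    "mean_heterozygosity",
    "run_experiment",
]


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Breeding-programme scenario parameters.

    Defaults are the full experimental design (smallest population level);
    tests and the acceptance script pass reduced-scale configs explicitly.
    """

    n_founders: int = 250
    n_chromosomes: int = 18
    sites_per_chr: int = 5400
    markers_per_chr: int = 1000
    n_qtl: int = 56  # total across the genome unless n_qtl_per_chr is set
    n_qtl_per_chr: int | None = None
    mean_dd: float = 0.0  # mean dominance degree (0 = purely additive trait)
    var_dd: float = 0.2
    h2_trait: float = 0.6  # narrow-sense h2 for burn-in phenotyping
    burn_in_cycles: int = 10
    n_cycles: int = 40
    n_crosses: int = 400
    progeny_per_cross: int | None = None  # default keeps census ~ n_founders
    stage_h2: tuple = (0.15, 0.25, 0.45, 0.65)
    stage_reps: tuple = (1, 2, 3, 3)
    stage_advance: tuple = (0.90, 0.80, 0.70, 0.60)
    map_length: float = 1.0  # Morgans per chromosome
    gebv_parent_divisor: int = 2  # chain-mate the top 2*n_crosses/k parents
    uc_selected_fraction: float | None = None  # None: n_crosses / candidate pairs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stage_h2", "stage_reps", "stage_advance"):
            if len(getattr(self, name)) != 4:
                raise SimError(f"{name} must list the 4 stages CE/PYT/AYT/UYT")
        if not all(0 < h < 1 for h in self.stage_h2):
            raise SimError("stage heritabilities must be in (0,1)")
        if not all(0 < a <= 1 for a in self.stage_advance):
            raise SimError("advancement fractions must be in (0,1]")
        if not 0 < self.h2_trait < 1:
            raise SimError("h2_trait must be in (0,1)")
        qtl_chr = self._qtl_per_chr()
        if max(qtl_chr) + self.markers_per_chr > self.sites_per_chr:
            raise SimError("QTL + marker panel exceed segregating sites per chromosome")

    def _qtl_per_chr(self) -> list[int]:
        if self.n_qtl_per_chr is not None:
            return [self.n_qtl_per_chr] * self.n_chromosomes
        base, extra = divmod(self.n_qtl, self.n_chromosomes)
        return [base + (1 if i < extra else 0) for i in range(self.n_chromosomes)]

    @property
    def progeny(self) -> int:
        if self.progeny_per_cross is not None:
            return self.progeny_per_cross
        return max(1, round(self.n_founders / self.n_crosses))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Population:
    """Diploid population: per-chromosome haplotypes plus the trait map.

    ``haplotypes[c]`` has shape (n, 2, L_c) with 0/1 alleles; the QTL/marker
    maps and effect vectors are shared across generations of one experiment.
    """

    haplotypes: list[np.ndarray]
    positions: list[np.ndarray]  # Morgan positions, sorted per chromosome
    qtl_idx: list[np.ndarray]
    qtl_add: list[np.ndarray]
    qtl_dom: list[np.ndarray]
    marker_idx: list[np.ndarray]
    g_intercept: float = 0.0
    founder_var_g: float = 1.0  # genetic variance at founding; fixes Ve per stage

    @property
    def n(self) -> int:
        return self.haplotypes[0].shape[0]

    def _dosages(self, idx_list: list[np.ndarray]) -> np.ndarray:
        return np.concatenate(
            [h[:, :, idx].sum(axis=1) for h, idx in zip(self.haplotypes, idx_list)],
            axis=1,
        )

    def qtl_dosages(self) -> np.ndarray:
        return self._dosages(self.qtl_idx)

    def marker_dosages(self) -> np.ndarray:
        return self._dosages(self.marker_idx)

    def genetic_values(self) -> np.ndarray:
        """True genotypic value: additive a_i (dosage-1) plus d_i if heterozygous."""
        g = np.zeros(self.n)
        for h, idx, a, d in zip(
            self.haplotypes, self.qtl_idx, self.qtl_add, self.qtl_dom
        ):
            dos = h[:, :, idx].sum(axis=1)
            g += (dos - 1.0) @ a + (dos == 1) @ d
        return g - self.g_intercept

    def with_haplotypes(self, haps: list[np.ndarray]) -> "Population":
        return Population(
            haplotypes=haps,
            positions=self.positions,
            qtl_idx=self.qtl_idx,
            qtl_add=self.qtl_add,
            qtl_dom=self.qtl_dom,
            marker_idx=self.marker_idx,
            g_intercept=self.g_intercept,
            founder_var_g=self.founder_var_g,
        )

    def to_genotype_matrix(self, prefix: str = "i") -> GenotypeMatrix:
        dos = self.marker_dosages()
        chroms, pos, mids = [], [], []
        for c, idx in enumerate(self.marker_idx):
            for k, site in enumerate(idx):
                chroms.append(str(c + 1))
                pos.append(int(site) + 1)
                mids.append(f"chr{c + 1}_m{k}")
        return GenotypeMatrix(
            individual_ids=[f"{prefix}{j}" for j in range(self.n)],
            marker_ids=mids,
            dosages=dos.astype(float),
            ploidy=2,
            chroms=chroms,
            positions=pos,
        )


def simulate_founders(cfg: SimConfig, rng: np.random.Generator) -> Population:
    """Draw founder haplotypes and the trait architecture.

    Sites get independent U-shaped (Beta(0.5, 0.5)) allele frequencies; QTL
    are sampled disjointly from the marker panel; additive effects are
    rescaled so the founder additive variance is exactly 1 and the founder
    mean genotypic value is 0.
    """
    n = cfg.n_founders
    qtl_per_chr = cfg._qtl_per_chr()
    haps, positions, qtl_idx, marker_idx = [], [], [], []
    for c in range(cfg.n_chromosomes):
        L = cfg.sites_per_chr
        freqs = np.clip(rng.beta(0.5, 0.5, size=L), 0.02, 0.98)
        haps.append((rng.random((n, 2, L)) < freqs).astype(np.uint8))
        positions.append(np.sort(rng.random(L)) * cfg.map_length)
        sites = rng.permutation(L)
        marker_idx.append(np.sort(sites[: cfg.markers_per_chr]))
        qtl_idx.append(
            np.sort(sites[cfg.markers_per_chr : cfg.markers_per_chr + qtl_per_chr[c]])
        )
    a_raw = [rng.normal(size=len(idx)) for idx in qtl_idx]
    A = np.zeros(n)
    for h, idx, a in zip(haps, qtl_idx, a_raw):
        A += (h[:, :, idx].sum(axis=1) - 1.0) @ a
    sd = A.std(ddof=0)
    if sd <= 0:
        raise SimError("all QTL monomorphic in founders; additive variance is zero")
    qtl_add = [a / sd for a in a_raw]
    sd_dd = float(np.sqrt(cfg.var_dd))
    qtl_dom = [
        np.abs(a) * rng.normal(cfg.mean_dd, sd_dd, size=len(a)) if sd_dd > 0
        else np.abs(a) * cfg.mean_dd
        for a in qtl_add
    ]
    pop = Population(
        haplotypes=haps,
        positions=positions,
        qtl_idx=qtl_idx,
        qtl_add=qtl_add,
        qtl_dom=qtl_dom,
        marker_idx=marker_idx,
        g_intercept=0.0,
    )
    pop.g_intercept = float(pop.genetic_values().mean())
    pop.founder_var_g = float(np.var(pop.genetic_values()))
    return pop


def meiosis(
    parent_haps: list[np.ndarray],
    positions: list[np.ndarray],
    rng: np.random.Generator,
    map_length: float = 1.0,
) -> list[np.ndarray]:
    """One gamete from a diploid parent: Poisson crossovers, no interference.

    ``parent_haps[c]`` has shape (2, L_c).  Crossover count per chromosome is
    Poisson(map length); breakpoints are uniform on the map.
    """
    gamete = []
    for haps, pos in zip(parent_haps, positions):
        n_cx = rng.poisson(map_length) if map_length > 0 else 0
        start = rng.integers(2)
        if n_cx == 0:
            gamete.append(haps[start].copy())
            continue
        cx = np.sort(rng.random(n_cx) * map_length)
        segment = (start + np.searchsorted(cx, pos)) % 2
        gamete.append(haps[segment, np.arange(haps.shape[1])])
    return gamete


def make_progeny(
    pop: Population,
    pairs: list[tuple[int, int]],
    progeny_per_cross: int,
    rng: np.random.Generator,
    map_length: float = 1.0,
) -> Population:
    """Generate the next generation from a list of parent-index pairs."""
    out = [
        np.empty((len(pairs) * progeny_per_cross, 2, h.shape[2]), dtype=np.uint8)
        for h in pop.haplotypes
    ]
    row = 0
    for j, k in pairs:
        p1 = [h[j] for h in pop.haplotypes]
        p2 = [h[k] for h in pop.haplotypes]
        for _ in range(progeny_per_cross):
            g1 = meiosis(p1, pop.positions, rng, map_length)
            g2 = meiosis(p2, pop.positions, rng, map_length)
            for c in range(len(out)):
                out[c][row, 0] = g1[c]
                out[c][row, 1] = g2[c]
            row += 1
    return pop.with_haplotypes(out)


def phenotype(
    g: np.ndarray,
    h2: float,
    n_reps: int,
    rng: np.random.Generator,
    var_g: float | None = None,
) -> np.ndarray:
    """Phenotype means: genotypic value plus the mean of n_reps plot errors.

    Plot error variance is Vg (1-h2)/h2, so single-plot heritability equals
    h2 in the reference cohort.  ``var_g`` defaults to the realized genetic
    variance of ``g``; the pipeline passes the *founder* genetic variance so
    error variances stay fixed across cycles (phenotyping precision does not
    improve as selection erodes variance).
    """
    if not 0 < h2 < 1:
        raise SimError("h2 must be in (0,1)")
    vg = float(np.var(g)) if var_g is None else float(var_g)
    if vg <= 1e-12:
        raise SimError("zero genetic variance; heritability undefined")
    ve = vg * (1 - h2) / h2
    return g + rng.normal(0.0, np.sqrt(ve / n_reps), size=g.shape)


def run_stage_pipeline(
    pop: Population, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Push a cohort through CE -> PYT -> AYT -> UYT.

    At each stage the current survivors are phenotyped at that stage's
    heritability and replication and the top fraction (on phenotype) advances.
    Returns (UYT survivor indices, per-individual training phenotype) where
    the training phenotype is the replication-weighted mean of the stage
    phenotypes each individual received (NaN for never-phenotyped — none here,
    every entrant is phenotyped at CE).
    """
    g = pop.genetic_values()
    alive = np.arange(pop.n)
    wsum = np.zeros(pop.n)
    ysum = np.zeros(pop.n)
    for h2, reps, adv in zip(cfg.stage_h2, cfg.stage_reps, cfg.stage_advance):
        if len(alive) < 2:
            break
        ph = phenotype(g[alive], h2, reps, rng, var_g=pop.founder_var_g)
        ysum[alive] += reps * ph
        wsum[alive] += reps
        # epsilon guards the floor against float error (0.7*720 != 504.0)
        n_keep = max(2, int(np.floor(adv * len(alive) + 1e-9)))
        keep = np.argsort(-ph, kind="stable")[:n_keep]
        alive = alive[np.sort(keep)]
    y_train = np.where(wsum > 0, ysum / np.maximum(wsum, 1e-12), np.nan)
    return alive, y_train


def selection_intensity(p: float) -> float:
    """Standardized selection intensity i = phi(z)/p for selected fraction p."""
    if not 0 < p < 1:
        raise SimError("selected fraction must be in (0,1)")
    z = stats.norm.ppf(1 - p)
    return float(stats.norm.pdf(z) / p)


def usefulness_criterion(values: np.ndarray, selected_fraction: float) -> float:
    """UC = mean(g) + i * sd(g) over progeny genotypic values."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise SimError("usefulness criterion needs at least 2 progeny values")
    sd = float(values.std(ddof=1))
    if sd == 0:
        return float(values.mean())
    return float(values.mean() + selection_intensity(selected_fraction) * sd)


def mean_heterozygosity(pop: Population) -> float:
    """Mean over individuals and marker-panel loci of the heterozygote indicator."""
    total = 0.0
    count = 0
    for h, idx in zip(pop.haplotypes, pop.marker_idx):
        dos = h[:, :, idx].sum(axis=1)
        total += float((dos == 1).sum())
        count += dos.size
    return total / count


def _fit_effects(
    pop: Population, y_train: np.ndarray, method: str
) -> dm.MarkerEffects:
    """Fit the genomic model on the cohort and back-solve marker effects.

    The GEBV arm fits additive-only GBLUP; the GPCP arm fits the full
    additive + directional-dominance model.
    """
    G = pop.to_genotype_matrix()
    pheno = pd.DataFrame({"germplasmName": G.individual_ids, "trait": y_train})
    with_dom = method == "gpcp"
    spec = dm.ModelSpec(
        response="trait",
        include_dominance=with_dom,
        include_directional_dominance=with_dom,
    )
    design = dm.build_design(pheno, G, spec)
    fit = dm.fit_reml(design, spec)
    return dm.marker_effects(fit, design, trait="trait")


def select_and_mate(
    pop: Population,
    candidates: np.ndarray,
    y_train: np.ndarray,
    method: str,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, int]], Population]:
    """Choose cfg.n_crosses parent pairs by GEBV or cross-merit and mate them.

    GEBV: candidates ranked on additive marker effects; the top
    2*n_crosses/k parents (k = cfg.gebv_parent_divisor) are chain-mated
    round-robin until n_crosses pairs are formed.  GPCP: all candidate pairs
    ranked on predicted F1 mean; the top n_crosses pairs are mated.  Both
    arms produce n_crosses * progeny_per_cross progeny.
    """
    if len(candidates) < 2:
        raise SimError("need at least 2 candidate parents")
    effects = _fit_effects(pop, y_train, method)
    G = pop.to_genotype_matrix()
    cand_ids = [G.individual_ids[j] for j in candidates]
    Gc = G.subset_individuals(cand_ids)
    if method == "gebv":
        scores = dm.gebv(effects, Gc)
        order = candidates[np.argsort(-scores, kind="stable")]
        n_par = int(np.ceil(2 * cfg.n_crosses / cfg.gebv_parent_divisor))
        top = order[: max(2, min(len(order), n_par))]
        pairs = []
        offset = 1
        while len(pairs) < cfg.n_crosses:
            for j in range(len(top)):
                pairs.append((int(top[j]), int(top[(j + offset) % len(top)])))
                if len(pairs) == cfg.n_crosses:
                    break
            offset += 1
            if offset >= len(top):  # exhausted distinct pairs; recycle
                offset = 1
    elif method == "gpcp":
        table = cp.predict_all(
            {"trait": effects}, Gc, n_crosses=cfg.n_crosses, allow_self=False
        )
        idx_of = {gid: int(j) for gid, j in zip(cand_ids, candidates)}
        pairs = [
            (idx_of[r.Parent1], idx_of[r.Parent2]) for r in table.itertuples()
        ]
    else:
        raise SimError(f"unknown selection method {method!r}")
    progeny = make_progeny(pop, pairs, cfg.progeny, rng, cfg.map_length)
    return pairs, progeny


def _cross_level_fraction(cfg: SimConfig, n_candidates: int) -> float:
    if cfg.uc_selected_fraction is not None:
        return cfg.uc_selected_fraction
    n_pairs = n_candidates * (n_candidates - 1) // 2
    return min(0.99, max(1e-6, cfg.n_crosses / max(n_pairs, cfg.n_crosses + 1)))


def run_experiment(cfg: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Run burn-in plus both selection arms; return the per-cycle trajectory.

    Burn-in cycles (numbered -(burn_in-1)..0) random-mate a shared population;
    both arms then advance independently from the bit-identical post-burn-in
    state.  Output columns: cycle, arm, uc, mean_het, delta_uc, delta_h (the
    deltas are GPCP minus GEBV, repeated on both arm rows of a cycle).
    """
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence(seed)
    rng_burn, rng_gebv, rng_gpcp = (np.random.default_rng(s) for s in ss.spawn(3))

    pop = simulate_founders(cfg, rng_burn)
    records = []
    for c in range(cfg.burn_in_cycles):
        parents = np.arange(pop.n)
        pairs = [
            tuple(rng_burn.choice(parents, size=2, replace=False))
            for _ in range(cfg.n_crosses)
        ]
        progeny = make_progeny(pop, pairs, cfg.progeny, rng_burn, cfg.map_length)
        # burn-in protocol includes phenotypic evaluation; it does not
        # influence mating, which stays random
        phenotype(progeny.genetic_values(), cfg.h2_trait, 1, rng_burn,
                  var_g=progeny.founder_var_g)
        frac = _cross_level_fraction(cfg, pop.n)
        uc = usefulness_criterion(progeny.genetic_values(), frac)
        het = mean_heterozygosity(progeny)
        cycle = c - cfg.burn_in_cycles + 1
        for arm in ("gebv", "gpcp"):
            records.append({"cycle": cycle, "arm": arm, "uc": uc, "mean_het": het})
        pop = progeny

    start = pop
    for arm, rng in (("gebv", rng_gebv), ("gpcp", rng_gpcp)):
        pop = start
        for c in range(1, cfg.n_cycles + 1):
            candidates, y_train = run_stage_pipeline(pop, cfg, rng)
            _, progeny = select_and_mate(pop, candidates, y_train, arm, cfg, rng)
            frac = _cross_level_fraction(cfg, len(candidates))
            uc = usefulness_criterion(progeny.genetic_values(), frac)
            het = mean_heterozygosity(progeny)
            records.append({"cycle": c, "arm": arm, "uc": uc, "mean_het": het})
            pop = progeny

    df = pd.DataFrame(records)
    wide = df.pivot_table(index="cycle", columns="arm", values=["uc", "mean_het"])
    delta_uc = (wide[("uc", "gpcp")] - wide[("uc", "gebv")]).rename("delta_uc")
    delta_h = (wide[("mean_het", "gpcp")] - wide[("mean_het", "gebv")]).rename("delta_h")
    df = df.merge(delta_uc, on="cycle").merge(delta_h, on="cycle")
    return df.sort_values(["cycle", "arm"]).reset_index(drop=True)
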