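"""Deterministic generators of small, self-consistent test inputs.

Every fixture is seeded and carries a *truth sidecar* — the exact effects,
variance components and fixed effects used to simulate it — so downstream
expected values can be computed without re-deriving anything.

Genotypes are drawn with a per-individual baseline inbreeding level
``F_j ~ U(0, 0.5)``: at each marker the individual is fully homozygous with
probability ``F_j`` (allele chosen at its panel frequency) and a
Hardy-Weinberg draw otherwise.  This emulates the spread of genomic
inbreeding seen in clonal-crop germplasm panels; without it the genomic
inbreeding covariate f is essentially constant across individuals and its
slope b is unidentifiable at any realistic sample size.

Phenotypes are simulated forward from the directional-dominance model
``y = X beta + f b + Z a + W d* + e`` with marker effects drawn at the same
scaling the fitting code uses, so REML recovery is measured on a common
parameterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import (
    GenotypeMatrix,
    heterozygosity_matrix,
    inbreeding_coefficients,
)

__all__ = ["FixtureSpec", "make_panel", "make_phenotypes", "write_formats"]


@dataclass
class FixtureSpec:
    n_individuals: int = 50
    n_markers: int = 200
    ploidy: int = 2
    true_var_additive: float = 1.0
    true_var_dominance: float = 0.5
    true_var_residual: float = 1.0
    true_b_inbreeding: float = -0.5
    fixed_factor_levels: dict[str, int] = field(default_factory=dict)
    max_baseline_inbreeding: float = 0.5
    genotype_id_column: str = "germplasmName"
    trait: str = "trait"
    seed: int = 0


def _scales(dosages: np.ndarray, ploidy: int) -> tuple[float, float]:
    pbar = dosages.mean(axis=0) / ploidy
    het = 2 * pbar * (1 - pbar)
    return float(np.sum(het) * ploidy / 2), float(max(np.sum(het**2), 1e-12))


def make_panel(spec: FixtureSpec) -> tuple[GenotypeMatrix, dict]:
    """Marker panel plus true per-marker effects.

    Dosages: with probability F_j the call is homozygous (dosage 0 or ploidy
    at the marker frequency), else binomial(ploidy, p_i) with
    p_i ~ U(0.05, 0.95).  True effects: a_i ~ N(0, sigma2_a / s_a),
    d*_i ~ N(0, sigma2_d / s_d) with the panel's realized scaling constants.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, rho = spec.n_individuals, spec.n_markers, spec.ploidy
    p = rng.uniform(0.05, 0.95, size=m)
    F = rng.uniform(0.0, spec.max_baseline_inbreeding, size=n)
    hw = rng.binomial(rho, p, size=(n, m)).astype(float)
    homo = rho * (rng.random((n, m)) < p)
    is_inbred = rng.random((n, m)) < F[:, None]
    dosages = np.where(is_inbred, homo, hw)
    G = GenotypeMatrix(
        individual_ids=[f"g{j:03d}" for j in range(n)],
        marker_ids=[f"m{i:04d}" for i in range(m)],
        dosages=dosages,
        ploidy=rho,
        chroms=["1"] * m,
        positions=list(range(1, m + 1)),
    )
    s_a, s_d = _scales(dosages, rho)
    a = rng.normal(0.0, np.sqrt(spec.true_var_additive / s_a), size=m)
    dstar = (
        rng.normal(0.0, np.sqrt(spec.true_var_dominance / s_d), size=m)
        if spec.true_var_dominance > 0
        else np.zeros(m)
    )
    truth = {
        "additive": a,
        "dominance_deviation": dstar,
        "b_inbreeding": spec.true_b_inbreeding,
        "var_additive": spec.true_var_additive,
        "var_dominance": spec.true_var_dominance,
        "var_residual": spec.true_var_residual,
        "scale_a": s_a,
        "scale_d": s_d,
        "allele_freqs": p,
    }
    return G, truth


def make_phenotypes(
    G: GenotypeMatrix, truth: dict, spec: FixtureSpec
) -> tuple[pd.DataFrame, dict]:
    """Simulate phenotype records forward from the directional-dominance model.

    One record per individual per combination of fixed-factor levels; factor
    level effects are drawn N(0, 1) and recorded in the truth sidecar.
    """
    rng = np.random.default_rng(spec.seed + 1)
    Zc = G.dosages - G.dosages.mean(axis=0)
    W = heterozygosity_matrix(G)
    Wc = W - W.mean(axis=0)
    f = inbreeding_coefficients(G)
    g_signal = (
        Zc @ truth["additive"]
        + Wc @ truth["dominance_deviation"]
        + f * truth["b_inbreeding"]
    )

    frames = [pd.DataFrame({spec.genotype_id_column: G.individual_ids})]
    factor_effects: dict[str, dict[str, float]] = {}
    df = frames[0]
    for fac, n_levels in spec.fixed_factor_levels.items():
        levels = [f"{fac}{k + 1}" for k in range(n_levels)]
        effs = rng.normal(0.0, 1.0, size=n_levels)
        effs[0] = 0.0  # first level is the reference
        factor_effects[fac] = dict(zip(levels, effs))
        df = df.merge(pd.DataFrame({fac: levels}), how="cross")
    n_rec = len(df)
    idx = df[spec.genotype_id_column].map(
        {g: j for j, g in enumerate(G.individual_ids)}
    ).to_numpy()
    y = g_signal[idx].astype(float)
    for fac in spec.fixed_factor_levels:
        y += df[fac].map(factor_effects[fac]).to_numpy()
    y += rng.normal(0.0, np.sqrt(spec.true_var_residual), size=n_rec)
    df[spec.trait] = y
    truth_out = dict(truth)
    truth_out["factor_effects"] = factor_effects
    truth_out["inbreeding_f"] = f
    return df, truth_out


_HOMO = {"A": "A", "C": "C", "G": "G", "T": "T"}
_IUPAC_OF = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def write_formats(
    G: GenotypeMatrix,
    phenotypes: pd.DataFrame | None,
    out_dir: str | Path,
    truth: dict | None = None,
    prefix: str = "fixture",
    hapmap: bool | None = None,
) -> dict[str, Path]:
    """Write paired VCF + (diploid) HapMap encodings plus phenotype/truth CSVs.

    The two genotype encodings describe the identical dosage matrix; reading
    either reproduces it exactly.  REF/counted alleles are A and C at every
    marker.  Polyploid HapMap output is refused: the format cannot encode
    partial polyploid dosage unambiguously.
    """
    if hapmap and G.ploidy != 2:
        raise ValueError(
            "HapMap output is unsupported for polyploids: the format cannot "
            "encode partial polyploid dosage"
        )
    if hapmap is None:
        hapmap = G.ploidy == 2
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    vcf = out_dir / f"{prefix}.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(G.chroms or ["1"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individual_ids) + "\n"
        )
        for i, mid in enumerate(G.marker_ids):
            chrom = G.chroms[i] if G.chroms else "1"
            pos = G.positions[i] if G.positions else i + 1
            calls = []
            for j in range(G.n_individuals):
                if G.missing_mask[j, i]:
                    calls.append("/".join(["."] * G.ploidy))
                else:
                    k = int(round(G.dosages[j, i]))
                    calls.append("/".join(["0"] * (G.ploidy - k) + ["1"] * k))
            fh.write(
                f"{chrom}\t{pos}\t{mid}\tA\tC\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )
    paths["vcf"] = vcf

    if hapmap:
        hmp = out_dir / f"{prefix}.hmp.txt"
        meta = ["strand", "assembly", "center", "protLSID", "assayLSID",
                "panelLSID", "QCcode"]
        with open(hmp, "w") as fh:
            fh.write(
                "rs#\talleles\tchrom\tpos\t" + "\t".join(meta) + "\t"
                + "\t".join(G.individual_ids) + "\n"
            )
            for i, mid in enumerate(G.marker_ids):
                chrom = G.chroms[i] if G.chroms else "1"
                pos = G.positions[i] if G.positions else i + 1
                calls = []
                for j in range(G.n_individuals):
                    if G.missing_mask[j, i]:
                        calls.append("NN")
                    else:
                        k = int(round(G.dosages[j, i]))
                        calls.append(["AA", "AC", "CC"][k])
                fh.write(
                    f"{mid}\tA/C\t{chrom}\t{pos}\t" + "\t".join(["NA"] * 7)
                    + "\t" + "\t".join(calls) + "\n"
                )
        paths["hapmap"] = hmp

    if phenotypes is not None:
        pcsv = out_dir / f"{prefix}_pheno.csv"
        phenotypes.to_csv(pcsv, index=False)
        paths["pheno"] = pcsv

    if truth is not None:
        tcsv = out_dir / f"{prefix}_truth.csv"
        pd.DataFrame(
            {
                "marker_id": G.marker_ids,
                "additive": truth["additive"],
                "dominance_deviation": truth["dominance_deviation"],
            }
        ).to_csv(tcsv, index=False)
        scsv = out_dir / f"{prefix}_truth_scalars.csv"
        scalars = {
            k: truth[k]
            for k in (
                "b_inbreeding", "var_additive", "var_dominance",
                "var_residual", "scale_a", "scale_d",
            )
        }
        pd.DataFrame([scalars]).to_csv(scsv, index=False)
        paths["truth"] = tcsv
        paths["truth_scalars"] = scsv
    return paths
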