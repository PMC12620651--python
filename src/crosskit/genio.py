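"""Ploidy-aware genotype I/O and the codings used by the cross-performance model.

Genotypes are held as allele *dosages*: the count of the tracked allele in
each genotype call, an integer in ``[0, ploidy]``.  For diploids dosages are
0/1/2; tetraploids and hexaploids use 0..4 and 0..6.  From the dosage matrix
this module derives the two codings the directional-dominance model consumes:

* the heterozygosity matrix ``W`` — for dosage ``k`` at ploidy ``rho`` the
  entry is ``k (rho - k) / C(rho, 2)``, the fraction of within-individual
  allele pairs that are heterozygous (0/1 for diploids);
* the genomic inbreeding coefficient ``f`` — one minus an individual's mean
  heterozygosity across markers, i.e. mean genomic homozygosity.

Supported input formats are VCF 4.x (GT or DS fields, any even ploidy) and
tab-delimited HapMap (diploid calls; polyploid calls only as explicit
allele strings, since IUPAC codes cannot express partial polyploid dosage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pysam

__all__ = [
    "GenotypeMatrix",
    "GenioError",
    "PloidyMismatchError",
    "ParseError",
    "EmptyPanelError",
    "read_vcf",
    "read_hapmap",
    "heterozygosity_matrix",
    "inbreeding_coefficients",
    "parental_frequencies",
    "filter_and_impute",
]


class GenioError(ValueError):
    """Base class for genotype-input errors."""


class ParseError(GenioError):
    """Malformed genotype file; message names the offending record."""


class PloidyMismatchError(GenioError):
    """Genotype call ploidy inconsistent with the declared ploidy."""


class EmptyPanelError(GenioError):
    """All markers removed by quality control."""


@dataclass
class GenotypeMatrix:
    """Allele dosages for n individuals at m markers, at a fixed even ploidy.

    ``dosages`` is float-valued so that mean-imputed entries can be carried;
    every *observed* entry is an integer in ``[0, ploidy]``.  ``missing_mask``
    is True where the original call was missing.  ``chroms``/``positions``
    are carried as metadata only (1-based, as in VCF).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    ploidy: int
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    chroms: list[str] | None = None
    positions: list[int] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenioError("dosages must be a 2-D (individuals x markers) array")
        n, m = self.dosages.shape
        if len(self.individual_ids) != n or len(self.marker_ids) != m:
            raise GenioError("id lists do not match dosage matrix shape")
        if len(set(self.individual_ids)) != n:
            raise GenioError("individual_ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise GenioError("marker_ids are not unique")
        if self.ploidy not in (2, 4, 6):
            raise GenioError(f"unsupported ploidy {self.ploidy}; expected 2, 4 or 6")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, m), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        obs = self.dosages[~self.missing_mask]
        if obs.size and (obs.min() < 0 or obs.max() > self.ploidy):
            raise GenioError("observed dosage outside [0, ploidy]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {g: i for i, g in enumerate(self.individual_ids)}
        missing = [g for g in ids if g not in index]
        if missing:
            raise GenioError(f"individuals absent from genotype matrix: {missing[:5]}")
        rows = [index[g] for g in ids]
        return GenotypeMatrix(
            individual_ids=list(ids),
            marker_ids=list(self.marker_ids),
            dosages=self.dosages[rows],
            ploidy=self.ploidy,
            missing_mask=self.missing_mask[rows],
            chroms=self.chroms,
            positions=self.positions,
        )


def read_vcf(path: str, ploidy: int = 2) -> GenotypeMatrix:
    """Read a VCF into dosages of the ALT allele.

    Uses the GT field (counting ALT alleles per call) when present, falling
    back to an integer-valued DS field.  Only biallelic sites are accepted.
    Calls with any missing allele are flagged in ``missing_mask``.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    marker_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    miss_rows: list[np.ndarray] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ParseError(
                f"site {rec.chrom}:{rec.pos} is not biallelic (ALT={rec.alts})"
            )
        dos = np.zeros(len(samples), dtype=float)
        miss = np.zeros(len(samples), dtype=bool)
        for j, name in enumerate(samples):
            call = rec.samples[name]
            gt = call.get("GT")
            if gt is not None and any(a is not None for a in gt):
                if len(gt) != ploidy or any(a is None for a in gt):
                    if all(a is None for a in gt):
                        miss[j] = True
                        continue
                    raise PloidyMismatchError(
                        f"site {rec.chrom}:{rec.pos} sample {name}: GT has "
                        f"{len(gt)} alleles, declared ploidy {ploidy}"
                    )
                dos[j] = sum(1 for a in gt if a == 1)
            elif "DS" in call and call["DS"] is not None:
                ds = float(call["DS"] if np.isscalar(call["DS"]) else call["DS"][0])
                if abs(ds - round(ds)) > 1e-6 or not 0 <= ds <= ploidy:
                    raise ParseError(
                        f"site {rec.chrom}:{rec.pos} sample {name}: DS value {ds} "
                        f"not an integer dosage in [0, {ploidy}]"
                    )
                dos[j] = round(ds)
            else:
                miss[j] = True
        marker_ids.append(rec.id if rec.id else f"{rec.chrom}_{rec.pos}")
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        rows.append(dos)
        miss_rows.append(miss)
    if not rows:
        raise ParseError(f"VCF {path} contains no variant records")
    return GenotypeMatrix(
        individual_ids=samples,
        marker_ids=marker_ids,
        dosages=np.array(rows).T,
        ploidy=ploidy,
        missing_mask=np.array(miss_rows).T,
        chroms=chroms,
        positions=positions,
    )


# IUPAC ambiguity codes for heterozygous diploid calls
_IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

_HAPMAP_META_COLS = 11


def read_hapmap(path: str, ploidy: int = 2) -> GenotypeMatrix:
    """Read a tab-delimited HapMap file.

    The 11 standard metadata columns precede the sample columns.  The counted
    allele is the *second* allele listed in the ``alleles`` column.  Calls may
    be explicit allele strings of length ``ploidy`` ("AC", "AACC", ...) or,
    for diploids only, a single IUPAC code.  "N" (any length) is missing.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) <= _HAPMAP_META_COLS:
            raise ParseError(f"{path}: HapMap header has no sample columns")
        samples = header[_HAPMAP_META_COLS:]
        marker_ids, chroms, positions = [], [], []
        rows, miss_rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} columns")
            alleles = fields[1].split("/")
            if len(alleles) != 2:
                raise ParseError(f"{path}:{lineno}: alleles field '{fields[1]}'")
            ref, counted = alleles
            dos = np.zeros(len(samples), dtype=float)
            miss = np.zeros(len(samples), dtype=bool)
            for j, call in enumerate(fields[_HAPMAP_META_COLS:]):
                call = call.strip().upper()
                if not call or set(call) == {"N"}:
                    miss[j] = True
                    continue
                if len(call) == 1 and call in _IUPAC_HET:
                    if ploidy != 2:
                        raise GenioError(
                            f"{path}:{lineno}: IUPAC heterozygote '{call}' cannot "
                            f"encode a partial dosage at ploidy {ploidy}"
                        )
                    pair = _IUPAC_HET[call]
                    if set(pair) != {ref, counted}:
                        raise ParseError(
                            f"{path}:{lineno}: IUPAC code '{call}' inconsistent "
                            f"with alleles {ref}/{counted}"
                        )
                    dos[j] = 1
                    continue
                if len(call) == 1 and call in (ref, counted):
                    call = call * ploidy  # single-letter homozygote shorthand
                if len(call) != ploidy:
                    raise PloidyMismatchError(
                        f"{path}:{lineno}: call '{call}' has {len(call)} alleles, "
                        f"declared ploidy {ploidy}"
                    )
                bad = set(call) - {ref, counted}
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: unknown allele code {sorted(bad)} "
                        f"(alleles {ref}/{counted})"
                    )
                dos[j] = call.count(counted)
            marker_ids.append(fields[0])
            chroms.append(fields[2])
            positions.append(int(fields[3]) if fields[3].isdigit() else 0)
            rows.append(dos)
            miss_rows.append(miss)
    if not rows:
        raise ParseError(f"{path}: HapMap file contains no marker rows")
    return GenotypeMatrix(
        individual_ids=samples,
        marker_ids=marker_ids,
        dosages=np.array(rows).T,
        ploidy=ploidy,
        missing_mask=np.array(miss_rows).T,
        chroms=chroms,
        positions=positions,
    )


def heterozygosity_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Per-call heterozygosity: k(rho-k)/C(rho,2) for dosage k, NaN if missing.

    This is the fraction of the C(rho,2) within-individual allele pairs that
    pair unlike alleles: 0/1 for diploids, e.g. 2/3 for a duplex tetraploid.
    """
    rho = G.ploidy
    W = G.dosages * (rho - G.dosages) / comb(rho, 2)
    W = np.where(G.missing_mask, np.nan, W)
    return W


def inbreeding_coefficients(G: GenotypeMatrix) -> np.ndarray:
    """Genomic inbreeding f: one minus mean heterozygosity over observed markers."""
    W = heterozygosity_matrix(G)
    n_obs = (~np.isnan(W)).sum(axis=1)
    if np.any(n_obs == 0):
        bad = [G.individual_ids[i] for i in np.where(n_obs == 0)[0]]
        raise GenioError(f"no observed markers for individuals: {bad[:5]}")
    return 1.0 - np.nanmean(W, axis=1)


def parental_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Within-parent allele frequency of the counted allele: dosage / ploidy.

    Missing entries propagate as NaN; run :func:`filter_and_impute` first if a
    complete matrix is needed.
    """
    p = G.dosages / G.ploidy
    return np.where(G.missing_mask, np.nan, p)


def filter_and_impute(
    G: GenotypeMatrix, min_maf: float = 0.0, max_missing: float = 1.0
) -> GenotypeMatrix:
    """Drop low-MAF / high-missingness markers, then mean-impute what remains.

    Allele frequencies and missing fractions are computed from observed calls
    only.  After imputation dosages are real-valued and ``missing_mask`` is
    all-False.  Heterozygosity and inbreeding should be derived *before*
    imputation (they use observed calls only).
    """
    if not 0 <= min_maf <= 0.5:
        raise GenioError("min_maf must be in [0, 0.5]")
    if not 0 <= max_missing <= 1:
        raise GenioError("max_missing must be in [0, 1]")
    d = np.where(G.missing_mask, np.nan, G.dosages)
    with np.errstate(invalid="ignore"):
        miss_frac = np.isnan(d).mean(axis=0)
        mean_dos = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    p = mean_dos / G.ploidy
    maf = np.minimum(p, 1 - p)
    keep = (~np.isnan(maf)) & (maf >= min_maf) & (miss_frac <= max_missing)
    if not keep.any():
        raise EmptyPanelError("all markers removed by MAF/missingness filters")
    d = d[:, keep]
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean[None, :], d)
    kept_idx = np.where(keep)[0]
    return GenotypeMatrix(
        individual_ids=list(G.individual_ids),
        marker_ids=[G.marker_ids[i] for i in kept_idx],
        dosages=d,
        ploidy=G.ploidy,
        missing_mask=np.zeros_like(d, dtype=bool),
        chroms=[G.chroms[i] for i in kept_idx] if G.chroms else None,
        positions=[G.positions[i] for i in kept_idx] if G.positions else None,
    )
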