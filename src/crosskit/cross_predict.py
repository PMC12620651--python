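"""Score candidate parent pairs with the closed-form F1-mean formula.

For one cross, with within-parent frequencies ``p_i`` (parent 1) and
``p'_i`` (parent 2) of the counted allele at marker i, ``q_i = 1 - p_i`` and
``y_i = p_i - p'_i``, the predicted mean genotypic value of the F1 family is

    M_F1 = sum_i [ a_i (p_i - q_i - y_i) + d_i (2 p_i q_i + y_i (p_i - q_i)) ]

which expands to ``a_i (p + p' - 1) + d_i (p + p' - 2 p p')`` — symmetric in
the two parents, and for diploids exactly the enumeration of the four gamete
combinations per locus.  It predicts the family *mean* only; segregation
variance within the family is not modelled.  The same formula is applied
unchanged to polyploid parents (frequencies ``dosage/ploidy``), without any
claim of equivalence to polysomic progeny enumeration beyond diploids.

Multi-trait merit is the selection-index weighted sum of per-trait means.
All n(n-1)/2 unordered pairs are scored (O(n^2 m)); scoring is blocked over
pairs so peak memory stays O(block x m) for large candidate sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import logging

import numpy as np
import pandas as pd

from .dirdom_model import MarkerEffects
from .genio import GenotypeMatrix, parental_frequencies

logger = logging.getLogger(__name__)

__all__ = ["SexCode", "sex_compatible", "cross_mean", "predict_all"]

#: sex codes: 1 = Male, 2 = Female, 3 = Monoecious male (m > f),
#: 4 = Monoecious female (f > m)
VALID_SEX_CODES = {1, 2, 3, 4}

SexCode = int


class CrossPredictError(ValueError):
    pass


def sex_compatible(s1: SexCode | None, s2: SexCode | None) -> bool:
    """Whether two parents can be mated given their sex codes.

    Dioecy rule: two males (1, 1) or two females (2, 2) are incompatible;
    monoecious plants (3, 4) and parents with no sex record mate with anyone.
    """
    for s in (s1, s2):
        if s is not None and s not in VALID_SEX_CODES:
            raise CrossPredictError(f"invalid sex code {s!r}; expected 1-4")
    if s1 is None or s2 is None:
        return True
    return not (s1 == s2 == 1 or s1 == s2 == 2)


def cross_mean(
    effects: MarkerEffects, p1: np.ndarray, p2: np.ndarray
) -> float:
    """Predicted mean genotypic value of the F1 of two parents.

    ``p1``/``p2`` are within-parent frequencies of the counted allele
    (dosage/ploidy), entries in [0, 1].
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    m = len(effects.marker_ids)
    if p1.shape != (m,) or p2.shape != (m,):
        raise CrossPredictError(
            f"parent frequency vectors must have length {m}; "
            f"got {p1.shape} and {p2.shape}"
        )
    q1 = 1.0 - p1
    y = p1 - p2
    add = effects.additive @ (p1 - q1 - y)
    dom = effects.dominance @ (2 * p1 * q1 + y * (p1 - q1))
    return float(add + dom)


def _pair_merits(a: np.ndarray, d: np.ndarray, P: np.ndarray,
                 block: int = 2048) -> np.ndarray:
    """Merit matrix for all ordered pairs, blocked over rows.

    M[j,k] = A_j + A_k - sum(a) + D_j + D_k - 2 (P diag(d) P')[j,k]
    with A = P a, D = P d (the expanded symmetric form of the F1 mean).
    """
    A = P @ a
    D = P @ d
    n = P.shape[0]
    out = np.empty((n, n))
    Pd = P * d  # n x m
    for start in range(0, n, block):
        stop = min(start + block, n)
        out[start:stop] = (
            A[start:stop, None] + A[None, :] - a.sum()
            + D[start:stop, None] + D[None, :]
            - 2.0 * Pd[start:stop] @ P.T
        )
    return out


def predict_all(
    effects_by_trait: dict[str, MarkerEffects] | list[MarkerEffects],
    G_parents: GenotypeMatrix,
    weights: dict[str, float] | None = None,
    sexes: dict[str, SexCode] | None = None,
    n_crosses: int = 100,
    allow_self: bool = False,
) -> pd.DataFrame:
    """Rank all candidate crosses by index-weighted predicted F1 mean.

    Returns a DataFrame with columns ID (1-based rank), Parent1, Parent2,
    merit (descending), plus sex1/sex2 when sex codes are supplied.  Pairs
    are stored with the lexicographically smaller parent first and ties are
    broken by (Parent1, Parent2), so output is a deterministic total order.
    """
    if isinstance(effects_by_trait, list):
        effects_by_trait = {e.trait or str(i): e for i, e in enumerate(effects_by_trait)}
    if weights is None:
        weights = {t: 1.0 for t in effects_by_trait}
    unknown = set(weights) - set(effects_by_trait)
    if unknown:
        raise CrossPredictError(f"weights for traits without effects: {sorted(unknown)}")
    if n_crosses < 1:
        raise CrossPredictError("n_crosses must be >= 1")
    marker_sets = {tuple(e.marker_ids) for e in effects_by_trait.values()}
    if len(marker_sets) != 1 or list(marker_sets)[0] != tuple(G_parents.marker_ids):
        raise CrossPredictError("all traits and parents must share one marker panel")
    if sexes is not None:
        for gid, s in sexes.items():
            if s not in VALID_SEX_CODES:
                raise CrossPredictError(f"invalid sex code {s!r} for {gid}")

    P = parental_frequencies(G_parents)
    if np.isnan(P).any():
        raise CrossPredictError("missing genotype calls among candidate parents")
    n = G_parents.n_individuals
    merit = np.zeros((n, n))
    for trait, eff in effects_by_trait.items():
        w = weights.get(trait, 0.0)
        if w:
            merit += w * _pair_merits(eff.additive, eff.dominance, P)

    ids = G_parents.individual_ids
    rows = []
    pair_iter = combinations(range(n), 2)
    if allow_self:
        pair_iter = list(pair_iter) + [(j, j) for j in range(n)]
    for j, k in pair_iter:
        g1, g2 = ids[j], ids[k]
        if g2 < g1:
            g1, g2, j, k = g2, g1, k, j
        s1 = sexes.get(g1) if sexes else None
        s2 = sexes.get(g2) if sexes else None
        if sexes is not None and not sex_compatible(s1, s2):
            continue
        rows.append((g1, g2, merit[j, k], s1, s2))
    if not rows:
        raise CrossPredictError("no sex-compatible candidate pairs")
    if n_crosses > len(rows):
        logger.warning(
            "requested %d crosses but only %d candidate pairs survive; "
            "returning all", n_crosses, len(rows),
        )
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    rows = rows[:n_crosses]
    out = pd.DataFrame(rows, columns=["Parent1", "Parent2", "merit", "sex1", "sex2"])
    out.insert(0, "ID", np.arange(1, len(out) + 1))
    if sexes is None:
        out = out.drop(columns=["sex1", "sex2"])
    return out
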