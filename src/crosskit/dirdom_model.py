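"""Additive + directional-dominance genomic mixed model, fitted by REML.

The model for trait phenotype means ``y`` is

    y = X beta + f b + Z a + W d* + e

with ``X`` the fixed-effect incidence matrix, ``f`` the genomic inbreeding
coefficient (mean homozygosity), ``b`` the inbreeding slope (directional
dominance: ``b < 0`` is inbreeding depression), ``Z`` mean-centred allele
dosages, ``W`` mean-centred heterozygosity codes, and marker effects
``a ~ N(0, I sigma2_a / s_a)``, ``d* ~ N(0, I sigma2_d / s_d)``,
``e ~ N(0, I sigma2_e)``.  The scaling constants are VanRaden-style sums
``s_a = sum_i 2 p_i q_i (rho/2)`` and ``s_d = sum_i (2 p_i q_i)^2`` so the
variance components are on the phenotypic scale.  This marker-effects (ridge)
parameterisation is equivalent to GBLUP with ``G_add = Z Z'/s_a`` and
``G_dom = W W'/s_d``; the relationship-matrix form is used as a test oracle.

Estimation is EM-REML with an average-information (AI) acceleration step:
each iteration proposes the AI update and falls back to the (monotone) EM
update whenever the AI step would leave the parameter space or decrease the
restricted likelihood, so the recorded log-likelihood trace is non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .genio import GenotypeMatrix, inbreeding_coefficients, heterozygosity_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "Design",
    "FittedModel",
    "MarkerEffects",
    "build_design",
    "fit_reml",
    "marker_effects",
    "gebv",
]

VARIANCE_FLOOR = 1e-8
REML_TOL = 1e-6
MAX_ITER = 200


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """What to fit: trait, factors, and which dominance terms to include.

    The genotype-ID factor is always random (its marker-based effects are the
    ``a``/``d*`` terms); ``random_factors`` lists *additional* iid random
    factors, each contributing one variance component.
    """

    response: str
    fixed_factors: list[str] = field(default_factory=list)
    random_factors: list[str] = field(default_factory=list)
    include_dominance: bool = True
    include_directional_dominance: bool = True
    trait_weights: dict[str, float] | None = None
    genotype_id_column: str = "germplasmName"


@dataclass
class Design:
    """Assembled y, X, f and centred marker codings, one row per record cell."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    f: np.ndarray | None
    Z: np.ndarray  # centred dosages, one row per observation
    W: np.ndarray | None  # centred heterozygosity codes
    scale_a: float
    scale_d: float
    center_z: np.ndarray
    center_w: np.ndarray
    marker_ids: list[str]
    obs_ids: list[str]  # genotype id of each observation row
    random_blocks: dict[str, np.ndarray] = field(default_factory=dict)
    ploidy: int = 2

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class FittedModel:
    """REML solution: variance components, fixed effects, and solver state."""

    beta: np.ndarray
    beta_names: list[str]
    b_inbreeding: float | None
    var_additive: float
    var_dominance: float | None
    var_residual: float
    var_random: dict[str, float]
    loglik_reml: float
    converged: bool
    n_iterations: int
    loglik_trace: np.ndarray
    Py: np.ndarray  # P y at the optimum; marker BLUPs back-solve from this

    def variance_summary(self) -> dict[str, float]:
        out = {"additive": self.var_additive, "residual": self.var_residual}
        if self.var_dominance is not None:
            out["dominance"] = self.var_dominance
        out.update(self.var_random)
        return out


@dataclass
class MarkerEffects:
    """Per-marker effects for one trait, ready for cross prediction.

    ``dominance`` is the total per-marker dominance effect used by the
    F1-mean formula: the dominance deviation ``d*_i`` plus the directional
    component ``-b/m`` (the inbreeding slope distributed over markers; with
    inbreeding depression ``b < 0`` this share is positive).
    """

    marker_ids: list[str]
    additive: np.ndarray
    dominance: np.ndarray
    dominance_deviation: np.ndarray
    b_inbreeding: float
    trait: str
    center_z: np.ndarray
    ploidy: int = 2


def _factor_matrix(df: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded incidence with intercept; aliased columns dropped."""
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for fac in factors:
        levels = sorted(df[fac].astype(str).unique())
        for lev in levels[1:]:
            cols.append((df[fac].astype(str) == lev).to_numpy(float))
            names.append(f"{fac}[{lev}]")
    X = np.column_stack(cols)
    # drop aliased (rank-deficient) columns via pivoted QR
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in piv[rank:]]
    if dropped:
        logger.warning("dropping aliased fixed-effect columns: %s", dropped)
    return X[:, keep], [names[i] for i in keep]


def build_design(pheno: pd.DataFrame, G: GenotypeMatrix, spec: ModelSpec) -> Design:
    """Join phenotypes to genotypes and assemble the model matrices.

    Replicate records are averaged per genotype x factor cell first, so y is
    a vector of phenotype means.  Z and W columns are centred on the training
    panel mean; the centring vectors are retained so candidate parents can be
    scored on the same scale.
    """
    idcol = spec.genotype_id_column
    for col in [idcol, spec.response] + spec.fixed_factors + spec.random_factors:
        if col not in pheno.columns:
            raise ModelError(f"column '{col}' not in phenotype table")
    pheno = pheno[[idcol, spec.response] + spec.fixed_factors + spec.random_factors]
    pheno = pheno.dropna(subset=[spec.response])
    geno_ids = set(G.individual_ids)
    have = pheno[idcol].astype(str).isin(geno_ids)
    n_dropped = int((~have).sum())
    if n_dropped:
        logger.info("dropping %d phenotype records without genotypes", n_dropped)
    pheno = pheno[have]
    if pheno.empty:
        raise ModelError("no overlap between phenotype IDs and genotype IDs")
    cell_cols = [idcol] + spec.fixed_factors + spec.random_factors
    cells = (
        pheno.groupby(cell_cols, sort=True, as_index=False)[spec.response].mean()
    )

    X, x_names = _factor_matrix(cells, spec.fixed_factors)

    ids = cells[idcol].astype(str).tolist()
    Gsub = G.subset_individuals(list(dict.fromkeys(ids)))
    if Gsub.missing_mask.any():
        raise ModelError(
            "genotype matrix has missing calls; run filter_and_impute first"
        )
    row_of = {g: i for i, g in enumerate(Gsub.individual_ids)}
    obs_rows = np.array([row_of[g] for g in ids])

    Z_u = Gsub.dosages
    center_z = Z_u.mean(axis=0)
    pbar = center_z / G.ploidy
    qbar = 1 - pbar
    scale_a = float(np.sum(2 * pbar * qbar) * (G.ploidy / 2))
    scale_d = float(np.sum((2 * pbar * qbar) ** 2))
    if scale_a <= 0:
        raise ModelError("monomorphic panel: additive scaling constant is zero")
    Zc = (Z_u - center_z)[obs_rows]

    W = f = None
    center_w = np.zeros(G.n_markers)
    if spec.include_dominance or spec.include_directional_dominance:
        W_u = heterozygosity_matrix(Gsub)
        f_u = inbreeding_coefficients(Gsub)
        center_w = W_u.mean(axis=0)
        W = (W_u - center_w)[obs_rows] if spec.include_dominance else None
        f = f_u[obs_rows] if spec.include_directional_dominance else None

    blocks = {}
    for fac in spec.random_factors:
        levels = sorted(cells[fac].astype(str).unique())
        B = np.zeros((len(cells), len(levels)))
        for k, lev in enumerate(levels):
            B[(cells[fac].astype(str) == lev).to_numpy(), k] = 1.0
        blocks[fac] = B

    return Design(
        y=cells[spec.response].to_numpy(float),
        X=X,
        x_names=x_names,
        f=f,
        Z=Zc,
        W=W,
        scale_a=scale_a,
        scale_d=max(scale_d, 1e-12),
        center_z=center_z,
        center_w=center_w,
        marker_ids=list(G.marker_ids),
        obs_ids=ids,
        random_blocks=blocks,
        ploidy=G.ploidy,
    )


def _component_grms(design: Design, spec: ModelSpec) -> tuple[list[str], list[np.ndarray]]:
    names = ["additive"]
    grms = [design.Z @ design.Z.T / design.scale_a]
    if spec.include_dominance and design.W is not None:
        names.append("dominance")
        grms.append(design.W @ design.W.T / design.scale_d)
    for fac, B in design.random_blocks.items():
        names.append(fac)
        grms.append(B @ B.T)
    return names, grms


def _reml_pieces(y, Xf, grms, theta):
    """Restricted log-likelihood and projection pieces at variance components
    theta = (components..., residual)."""
    n = y.shape[0]
    V = theta[-1] * np.eye(n)
    for t, Gk in zip(theta[:-1], grms):
        V += t * Gk
    cf = linalg.cho_factor(V, lower=True)
    logdet_v = 2 * np.sum(np.log(np.diag(cf[0])))
    Vinv_X = linalg.cho_solve(cf, Xf)
    XtVinvX = Xf.T @ Vinv_X
    cfx = linalg.cho_factor(XtVinvX)
    logdet_x = 2 * np.sum(np.log(np.diag(cfx[0])))
    Vinv_y = linalg.cho_solve(cf, y)
    beta = linalg.cho_solve(cfx, Xf.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
    # P = Vinv - Vinv X (X'VinvX)^-1 X'Vinv, built explicitly for traces
    Vinv = linalg.cho_solve(cf, np.eye(n))
    P = Vinv - Vinv_X @ linalg.cho_solve(cfx, Vinv_X.T)
    return ll, P, Py, beta


def fit_reml(design: Design, spec: ModelSpec, *, max_iter: int = MAX_ITER,
             tol: float = REML_TOL) -> FittedModel:
    """Estimate variance components by EM-REML with AI acceleration.

    The fb covariate joins the fixed part; if f is (numerically) constant the
    inbreeding slope is aliased with the intercept and dropped with a warning.
    Components hitting the 1e-8 floor are pinned there and logged.
    """
    y = design.y
    Xf = design.X
    x_names = list(design.x_names)
    use_b = spec.include_directional_dominance and design.f is not None
    if use_b and np.std(design.f) < 1e-10:
        logger.warning(
            "inbreeding covariate f is constant; dropping the directional "
            "dominance slope b (aliased with the intercept)"
        )
        use_b = False
    if use_b:
        Xf = np.column_stack([Xf, design.f])
        x_names = x_names + ["f(inbreeding)"]
    if y.shape[0] < Xf.shape[1] + 3:
        raise ModelError(
            f"too few observations ({y.shape[0]}) for {Xf.shape[1]} fixed effects"
        )

    comp_names, grms = _component_grms(design, spec)
    n = y.shape[0]
    vy = float(np.var(y, ddof=1))
    k = len(grms)
    theta = np.array([0.5 * vy / k] * k + [0.5 * vy])

    ll, P, Py, beta = _reml_pieces(y, Xf, grms, theta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        all_g = grms + [np.eye(n)]
        gPy = [Gk @ Py for Gk in all_g]
        quad = np.array([float(Py @ v) for v in gPy])
        tr_pg = np.array(
            [float(np.sum(P * Gk)) for Gk in grms] + [float(np.trace(P))]
        )
        score = -0.5 * (tr_pg - quad)
        # average-information matrix: 0.5 (G_j Py)' P (G_k Py)
        PgPy = [P @ v for v in gPy]
        AI = 0.5 * np.array(
            [[float(gPy[j] @ PgPy[kk]) for kk in range(k + 1)] for j in range(k + 1)]
        )
        accepted = None
        try:
            step = np.linalg.solve(AI + 1e-10 * np.eye(k + 1), score)
            cand = np.maximum(theta + step, VARIANCE_FLOOR)
            pieces = _reml_pieces(y, Xf, grms, cand)
            if pieces[0] >= ll - 1e-12:
                accepted = (cand, pieces)
        except np.linalg.LinAlgError:
            pass
        if accepted is None:
            cand = np.maximum(theta + theta**2 / n * (quad - tr_pg), VARIANCE_FLOOR)
            pieces = _reml_pieces(y, Xf, grms, cand)
            accepted = (cand, pieces)
        theta, (ll_new, P, Py, beta) = accepted
        trace.append(ll_new)
        if abs(ll_new - ll) < tol * (1 + abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)
    pinned = [comp_names[i] for i in range(k) if theta[i] <= VARIANCE_FLOOR * 1.01]
    if pinned:
        logger.info("variance components at lower bound: %s", pinned)

    var = dict(zip(comp_names, theta[:k]))
    b = float(beta[-1]) if use_b else None
    logger.info(
        "REML fit: %s, residual=%.4g, loglik=%.4f, iterations=%d",
        {nm: round(v, 4) for nm, v in var.items()}, theta[-1], ll, it,
    )
    return FittedModel(
        beta=beta[: len(design.x_names)] if use_b else beta,
        beta_names=list(design.x_names),
        b_inbreeding=b,
        var_additive=float(var["additive"]),
        var_dominance=float(var["dominance"]) if "dominance" in var else None,
        var_residual=float(theta[-1]),
        var_random={nm: float(var[nm]) for nm in var if nm not in ("additive", "dominance")},
        loglik_reml=float(ll),
        converged=converged,
        n_iterations=it,
        loglik_trace=np.array(trace),
        Py=Py,
    )


def marker_effects(fit: FittedModel, design: Design, trait: str = "") -> MarkerEffects:
    """Back-solve per-marker BLUPs from the fitted model.

    In the ridge parameterisation the additive BLUP is
    ``a_hat = (sigma2_a / s_a) Z' P y`` and likewise for the dominance
    deviation through W.  The directional component is folded in as
    ``d_i = d*_i - b/m`` (see :class:`MarkerEffects`).
    """
    a = (fit.var_additive / design.scale_a) * (design.Z.T @ fit.Py)
    m = design.n_markers
    if design.W is not None and fit.var_dominance is not None:
        dstar = (fit.var_dominance / design.scale_d) * (design.W.T @ fit.Py)
    else:
        dstar = np.zeros(m)
    b = fit.b_inbreeding if fit.b_inbreeding is not None else 0.0
    d = dstar - b / m
    return MarkerEffects(
        marker_ids=list(design.marker_ids),
        additive=a,
        dominance=d,
        dominance_deviation=dstar,
        b_inbreeding=b,
        trait=trait,
        center_z=design.center_z.copy(),
        ploidy=design.ploidy,
    )


def gebv(effects: MarkerEffects, G: GenotypeMatrix) -> np.ndarray:
    """Genomic estimated breeding values: centred dosages times additive effects."""
    if list(G.marker_ids) != list(effects.marker_ids):
        missing = set(effects.marker_ids) - set(G.marker_ids)
        raise ModelError(
            f"marker panel mismatch; {len(missing)} effect markers absent "
            f"(e.g. {sorted(missing)[:3]})"
        )
    Zc = G.dosages - effects.center_z
    return Zc @ effects.additive
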