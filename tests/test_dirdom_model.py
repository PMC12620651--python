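"""Directional-dominance mixed model: design assembly, REML, marker BLUPs."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from crosskit import dirdom_model as dm
from crosskit import fixtures as fx
from crosskit import genio


def _indep_reml_loglik(y, X, grms, theta):
    """Restricted log-likelihood via slogdet — independent of the solver path."""
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], grms):
        V += t * G
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtViX, X.T @ Vinv @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + float(r @ Vinv @ r)
    )


def _indep_reml_fit(y, X, grms, x0):
    """Direct Nelder-Mead REML on log-variances: the oracle estimator."""
    res = minimize(
        lambda lt: -_indep_reml_loglik(y, X, grms, np.exp(lt)),
        np.log(x0),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    return np.exp(res.x), -res.fun


@pytest.fixture(scope="module")
def identified_panel():
    """n > m panel where all three variance components are well identified
    (with m >> n the additive kernel can absorb the residual)."""
    spec = fx.FixtureSpec(n_individuals=120, n_markers=80, seed=17)
    G, truth = fx.make_panel(spec)
    pheno, truth = fx.make_phenotypes(G, truth, spec)
    return G, pheno, truth, spec


class TestBuildDesign:
    def test_intercept_only(self, small_panel):
        G, pheno, _, spec = small_panel
        ms = dm.ModelSpec(response=spec.trait)
        d = dm.build_design(pheno, G, ms)
        assert d.X.shape == (50, 1)
        assert np.all(d.X == 1.0)
        assert np.allclose(d.Z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(d.W.mean(axis=0), 0, atol=1e-10)

    def test_two_level_factor_treatment_coded(self):
        spec = fx.FixtureSpec(
            n_individuals=4, n_markers=5, seed=1, fixed_factor_levels={"loc": 2}
        )
        G, truth = fx.make_panel(spec)
        pheno, _ = fx.make_phenotypes(G, truth, spec)
        ms = dm.ModelSpec(response="trait", fixed_factors=["loc"])
        d = dm.build_design(pheno, G, ms)
        assert d.X.shape == (8, 2)  # 4 genotypes x 2 cells, intercept + contrast
        assert d.x_names == ["(Intercept)", "loc[loc2]"]

    def test_replicates_averaged_per_cell(self, small_panel):
        G = small_panel[0]
        pheno = pd.DataFrame(
            {
                "germplasmName": ["g000", "g000", "g001"],
                "trait": [1.0, 3.0, 5.0],
            }
        )
        ms = dm.ModelSpec(response="trait")
        d = dm.build_design(pheno, G, ms)
        assert sorted(d.y.tolist()) == [2.0, 5.0]

    def test_empty_join_errors(self, small_panel):
        G = small_panel[0]
        pheno = pd.DataFrame({"germplasmName": ["nope"], "trait": [1.0]})
        with pytest.raises(dm.ModelError, match="overlap"):
            dm.build_design(pheno, G, dm.ModelSpec(response="trait"))


class TestFitReml:
    def test_matches_independent_optimizer(self, identified_panel):
        """Dual route: EM/AI solution vs direct Nelder-Mead on the same REML
        surface computed with an independent likelihood implementation."""
        G, pheno, _, spec = identified_panel
        ms = dm.ModelSpec(response=spec.trait)
        d = dm.build_design(pheno, G, ms)
        fit = dm.fit_reml(d, ms)
        Xf = np.column_stack([d.X, d.f])
        grms = [d.Z @ d.Z.T / d.scale_a, d.W @ d.W.T / d.scale_d]
        theta0 = np.array([fit.var_additive, fit.var_dominance, fit.var_residual])
        theta_opt, ll_opt = _indep_reml_fit(d.y, Xf, grms, np.full(3, np.var(d.y) / 3))
        assert fit.loglik_reml == pytest.approx(ll_opt, abs=1e-3)
        np.testing.assert_allclose(theta0, theta_opt, rtol=0.05, atol=1e-3)

    def test_additive_only_matches_oracle(self, small_panel):
        """With dominance terms off the fit is plain additive GBLUP."""
        G, pheno, _, spec = small_panel
        ms = dm.ModelSpec(
            response=spec.trait,
            include_dominance=False,
            include_directional_dominance=False,
        )
        d = dm.build_design(pheno, G, ms)
        fit = dm.fit_reml(d, ms)
        grms = [d.Z @ d.Z.T / d.scale_a]
        theta_opt, ll_opt = _indep_reml_fit(
            d.y, d.X, grms, np.full(2, np.var(d.y) / 2)
        )
        assert fit.var_dominance is None and fit.b_inbreeding is None
        assert fit.loglik_reml == pytest.approx(ll_opt, abs=1e-3)
        np.testing.assert_allclose(
            [fit.var_additive, fit.var_residual], theta_opt, rtol=0.05
        )

    def test_loglik_monotone(self, small_panel):
        G, pheno, _, spec = small_panel
        ms = dm.ModelSpec(response=spec.trait)
        d = dm.build_design(pheno, G, ms)
        fit = dm.fit_reml(d, ms)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_null_dominance_component_shrinks(self):
        spec = fx.FixtureSpec(
            n_individuals=500, n_markers=300, seed=21,
            true_var_dominance=0.0, true_b_inbreeding=0.0,
        )
        G, truth = fx.make_panel(spec)
        pheno, _ = fx.make_phenotypes(G, truth, spec)
        ms = dm.ModelSpec(response="trait")
        d = dm.build_design(pheno, G, ms)
        fit = dm.fit_reml(d, ms)
        assert fit.var_dominance < 0.15 * fit.var_additive

    def test_fully_inbred_panel_drops_b(self, caplog):
        """All-homozygous panel: W = 0, f constant, so b is aliased away."""
        rng = np.random.default_rng(3)
        dos = 2.0 * rng.integers(0, 2, size=(30, 40))
        G = genio.GenotypeMatrix(
            [f"g{j}" for j in range(30)], [f"m{i}" for i in range(40)], dos, 2
        )
        pheno = pd.DataFrame(
            {"germplasmName": G.individual_ids, "trait": rng.normal(size=30)}
        )
        ms = dm.ModelSpec(response="trait")
        d = dm.build_design(pheno, G, ms)
        with caplog.at_level("WARNING", logger="crosskit.dirdom_model"):
            fit = dm.fit_reml(d, ms)
        assert fit.b_inbreeding is None
        assert "aliased" in caplog.text


class TestMarkerEffects:
    def test_single_marker_closed_form_ridge(self):
        """On a 3-point design the additive BLUP equals the closed-form ridge
        solution a = z'y / (z'z + lambda), lambda = sigma2_e * s_a / sigma2_a."""
        dos = np.array([[0.0], [1.0], [2.0]])
        y = np.array([0.0, 1.0, 2.0])  # exactly linear in dosage
        G = genio.GenotypeMatrix(["a", "b", "c"], ["m"], dos, 2)
        pheno = pd.DataFrame({"germplasmName": ["a", "b", "c"], "trait": y})
        ms = dm.ModelSpec(
            response="trait",
            include_dominance=False,
            include_directional_dominance=False,
        )
        d = dm.build_design(pheno, G, ms)
        va, ve = 2.0, 0.5
        from crosskit.dirdom_model import _reml_pieces
        _, _, Py, _ = _reml_pieces(y, d.X, [d.Z @ d.Z.T / d.scale_a],
                                   np.array([va, ve]))
        a_pkg = (va / d.scale_a) * float(d.Z[:, 0] @ Py)
        zc = d.Z[:, 0]
        lam = ve * d.scale_a / va
        a_ridge = float(zc @ (y - y.mean())) / (float(zc @ zc) + lam)
        assert a_pkg == pytest.approx(a_ridge, abs=1e-10)

    def test_gblup_duality(self, small_panel):
        """Individual additive BLUPs from the relationship-matrix form equal
        Z_c times the back-solved marker effects."""
        G, pheno, _, spec = small_panel
        ms = dm.ModelSpec(response=spec.trait)
        d = dm.build_design(pheno, G, ms)
        fit = dm.fit_reml(d, ms)
        eff = dm.marker_effects(fit, d)
        Ga = d.Z @ d.Z.T / d.scale_a
        u_add = fit.var_additive * (Ga @ fit.Py)
        np.testing.assert_allclose(d.Z @ eff.additive, u_add, atol=1e-6)

    def test_zero_dominance_gives_uniform_directional_share(self, small_panel):
        G, pheno, _, spec = small_panel
        ms = dm.ModelSpec(response=spec.trait)
        d = dm.build_design(pheno, G, ms)
        fit = dm.fit_reml(d, ms)
        fit.var_dominance = 0.0  # pin the deviation component
        eff = dm.marker_effects(fit, d)
        m = len(eff.marker_ids)
        np.testing.assert_allclose(
            eff.dominance, -eff.b_inbreeding / m * np.ones(m), atol=1e-12
        )

    def test_allele_coding_invariance(self, identified_panel):
        """Flipping the counted allele at any markers leaves GEBVs unchanged
        after re-estimation."""
        G, pheno, _, spec = identified_panel
        ms = dm.ModelSpec(response=spec.trait)

        def fit_gebv(Gx):
            d = dm.build_design(pheno, Gx, ms)
            fit = dm.fit_reml(d, ms)
            return dm.gebv(dm.marker_effects(fit, d), Gx)

        rng = np.random.default_rng(0)
        flip = rng.random(G.n_markers) < 0.5
        dos2 = G.dosages.copy()
        dos2[:, flip] = G.ploidy - dos2[:, flip]
        G2 = genio.GenotypeMatrix(
            list(G.individual_ids), list(G.marker_ids), dos2, G.ploidy
        )
        np.testing.assert_allclose(fit_gebv(G), fit_gebv(G2), atol=1e-6)


class TestGebv:
    def test_hand_dot_product(self):
        dos = np.array([[2.0, 0.0], [0.0, 2.0]])  # centred rows (1,-1), (-1,1)
        G = genio.GenotypeMatrix(["a", "b"], ["m1", "m2"], dos, 2)
        eff = dm.MarkerEffects(
            marker_ids=["m1", "m2"],
            additive=np.array([0.5, 0.2]),
            dominance=np.zeros(2),
            dominance_deviation=np.zeros(2),
            b_inbreeding=0.0,
            trait="t",
            center_z=np.array([1.0, 1.0]),
        )
        np.testing.assert_allclose(dm.gebv(eff, G), [0.3, -0.3])

    def test_mean_individual_scores_zero(self, small_panel):
        G, pheno, _, spec = small_panel
        ms = dm.ModelSpec(response=spec.trait)
        d = dm.build_design(pheno, G, ms)
        fit = dm.fit_reml(d, ms)
        eff = dm.marker_effects(fit, d)
        mean_row = genio.GenotypeMatrix(
            ["mean"], list(G.marker_ids),
            G.dosages.mean(axis=0, keepdims=True), 2,
        )
        # the panel-mean genotype scores zero by centring; zero effects too
        assert dm.gebv(eff, mean_row)[0] == pytest.approx(0.0, abs=1e-9)
        eff.additive = np.zeros_like(eff.additive)
        assert np.all(dm.gebv(eff, G) == 0)

    def test_marker_mismatch_errors(self, small_panel):
        G, pheno, _, spec = small_panel
        eff = dm.MarkerEffects(
            marker_ids=["absent1", "absent2"],
            additive=np.zeros(2),
            dominance=np.zeros(2),
            dominance_deviation=np.zeros(2),
            b_inbreeding=0.0,
            trait="t",
            center_z=np.zeros(2),
        )
        with pytest.raises(dm.ModelError, match="absent"):
            dm.gebv(eff, G)
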