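"""Animal-model REML: design building, profile likelihood, identifiability
and GLS fixed effects."""

import numpy as np
import pandas as pd
import pytest

from gpcattle.data import PhenotypeTable
from gpcattle.kinship import GRM, vanraden_grm
from gpcattle.reml import (build_fixed_design, estimate_fixed_effects,
                           fit_reml, _profile_reml)
from gpcattle.simulate import (SimulationConfig, simulate_dataset,
                               simulate_genotypes, simulate_marker_effects,
                               simulate_phenotypes)


def _pheno(n, genders=2, farms=1, years=1, rng=None):
    rng = rng or np.random.default_rng(1)
    return PhenotypeTable(pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "gender": [f"g{k}" for k in rng.integers(genders, size=n)],
        "farm": [f"f{k}" for k in rng.integers(farms, size=n)],
        "year": [str(2008 + k) for k in rng.integers(years, size=n)],
        "age": rng.uniform(540, 720, n),
        "trait": rng.normal(size=n),
    }))


class TestFixedDesign:
    def test_two_genders_single_farm_year_no_age(self):
        X, names, _ = build_fixed_design(_pheno(40), "trait", use_age=False)
        assert X.shape[1] == 2
        assert names[0] == "intercept"

    def test_age_column_optional(self):
        X_age, names, _ = build_fixed_design(_pheno(40), "trait", use_age=True)
        assert "age" in names
        X_no, names_no, _ = build_fixed_design(_pheno(40), "trait",
                                               use_age=False)
        assert "age" not in names_no
        assert X_age.shape[1] == X_no.shape[1] + 1

    def test_constant_factor_contributes_no_column(self):
        tab = _pheno(30, genders=1, farms=1, years=1)
        X, names, _ = build_fixed_design(tab, "trait", use_age=False)
        assert names == ["intercept"]

    def test_full_column_rank(self):
        X, _, _ = build_fixed_design(_pheno(200, genders=2, farms=5, years=6),
                                     "trait")
        assert np.linalg.matrix_rank(X) == X.shape[1]


def _simulated_reml_fixture(n=200, m=800, h2=0.5, seed=31):
    cfg = SimulationConfig(n_individuals=n, n_markers=m,
                           heritability_true=h2, architecture="normal",
                           ld_decay=0.95, seed=seed)
    geno, pheno, truth = simulate_dataset(cfg)
    grm = vanraden_grm(geno)
    X, _, _ = build_fixed_design(pheno, "trait")
    return pheno.trait("trait"), X, grm, truth


def _direct_restricted_loglik(sigma_a2, sigma_e2, y, X, G):
    """Independent dense evaluation of the restricted likelihood."""
    n, p = X.shape
    V = sigma_a2 * G + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ b
    return -0.5 * (np.linalg.slogdet(V)[1]
                   + np.linalg.slogdet(XtViX)[1]
                   + r @ Vi @ r + (n - p) * np.log(2 * np.pi))


class TestProfileReml:
    def test_agrees_with_direct_two_parameter_optimum(self):
        y, X, grm, _ = _simulated_reml_fixture(n=150, m=600)
        vc = fit_reml(y, X, grm)
        from scipy.optimize import minimize
        res = minimize(
            lambda t: -_direct_restricted_loglik(np.exp(t[0]), np.exp(t[1]),
                                                 y, X, grm.values),
            x0=[np.log(max(vc.sigma_a2, 1e-4) * 1.7),
                np.log(vc.sigma_e2 * 0.6)],
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        sa2, se2 = np.exp(res.x)
        assert abs(sa2 / (sa2 + se2) - vc.h2) < 1e-4

    def test_no_better_point_on_lambda_grid(self):
        y, X, grm, _ = _simulated_reml_fixture(n=120, m=500, seed=32)
        vc = fit_reml(y, X, grm)
        d, U = np.linalg.eigh(grm.values)
        d = np.clip(d, 0, None)
        yt, Xt = U.T @ y, U.T @ X
        for lam in np.logspace(-3, 3, 21):
            ll, _, _ = _profile_reml(lam, d, yt, Xt)
            assert ll <= vc.loglik + 1e-8

    def test_scale_invariance_of_h2(self):
        y, X, grm, _ = _simulated_reml_fixture(n=120, m=500, seed=33)
        vc1 = fit_reml(y, X, grm)
        vc2 = fit_reml(10.0 * y, X, grm)
        assert abs(vc1.h2 - vc2.h2) < 1e-6
        assert vc2.sigma_a2 == pytest.approx(100 * vc1.sigma_a2, rel=1e-4)

    def test_identity_grm_rejected_as_non_identifiable(self, rng):
        n = 60
        grm = GRM(np.eye(n), [f"s{i}" for i in range(n)], 1.0)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        with pytest.raises(ValueError, match="identifiab"):
            fit_reml(y, X, grm)

    def test_zero_heritability_flagged_at_boundary(self):
        cfg = SimulationConfig(n_individuals=150, n_markers=400,
                               heritability_true=0.5, ld_decay=0.95, seed=34)
        geno = simulate_genotypes(cfg)
        grm = vanraden_grm(geno)
        rng = np.random.default_rng(0)
        y = rng.normal(size=150)           # no genetic signal at all
        X = np.ones((150, 1))
        vc = fit_reml(y, X, grm)
        assert vc.h2 < 0.05
        assert vc.at_boundary or vc.h2 < 0.05

    def test_non_finite_y_rejected(self):
        y, X, grm, _ = _simulated_reml_fixture(n=60, m=200, seed=35)
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_reml(y, X, grm)

    def test_se_positive(self):
        y, X, grm, _ = _simulated_reml_fixture(n=150, m=600, seed=36)
        vc = fit_reml(y, X, grm)
        assert vc.se_h2 > 0


class TestFixedEffects:
    def test_permutation_equivariance(self):
        y, X, grm, _ = _simulated_reml_fixture(n=100, m=400, seed=37)
        vc = fit_reml(y, X, grm)
        b1 = estimate_fixed_effects(y, X, grm, vc)
        perm = np.random.default_rng(5).permutation(len(y))
        g2 = GRM(grm.values[np.ix_(perm, perm)], grm.sample_ids[perm],
                 grm.denominator)
        b2 = estimate_fixed_effects(y[perm], X[perm], g2, vc)
        np.testing.assert_allclose(b1, b2, rtol=1e-8)

    def test_recovers_simulated_effects_within_3_se(self):
        cfg = SimulationConfig(n_individuals=300, n_markers=500,
                               heritability_true=0.4, ld_decay=0.95, seed=38)
        geno, pheno, truth = simulate_dataset(cfg)
        grm = vanraden_grm(geno)
        X, names, _ = build_fixed_design(pheno, "trait")
        vc = fit_reml(pheno.trait("trait"), X, grm)
        b = estimate_fixed_effects(pheno.trait("trait"), X, grm, vc)
        # the intercept absorbs reference levels; check the age slope,
        # which is identified directly
        V = vc.sigma_a2 * grm.values + vc.sigma_e2 * np.eye(300)
        cov_b = np.linalg.inv(X.T @ np.linalg.solve(V, X))
        j = names.index("age")
        assert abs(b[j] - truth.fixed_effects[-1]) < 3 * np.sqrt(cov_b[j, j])
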