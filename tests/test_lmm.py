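"""Variance-component likelihood, its dense oracle, and ML fitting."""

import numpy as np
import pytest
from scipy.stats import norm

from methvc.cli import _design
from methvc.lmm import (
    VarCompModel,
    fit_ml,
    fit_null_and_full,
    loglikelihood,
)
from methvc.pedigree import additive_matrix, kinship_matrix
from methvc.simulate import desk_preset, simulate_pedigree, simulate_trait


def random_psd(rng, n):
    A = rng.standard_normal((n, n + 2))
    K = A @ A.T
    d = np.sqrt(np.diag(K))
    return K / np.outer(d, d)


def dense_loglik(y, X, betas, Omega):
    """Independent closed-form oracle: -1/2 [n log 2pi + log|O| + r' O^-1 r]."""
    r = y - X @ betas
    sign, logdet = np.linalg.slogdet(Omega)
    assert sign > 0
    return -0.5 * (y.size * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(Omega, r))


class TestLoglikelihood:
    def test_diagonal_case_equals_independent_normals(self):
        y = np.array([0.3, -1.2, 2.0])
        X = np.ones((3, 1))
        K = random_psd(np.random.default_rng(0), 3)
        model = VarCompModel(y, X, [("k", K)])
        ll = loglikelihood(model, [0.0], sigma2=1.0, betas=[0.0])
        assert ll == pytest.approx(norm.logpdf(y).sum(), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        kernels = [("a", random_psd(rng, n)), ("b", random_psd(rng, n))]
        f = rng.dirichlet([1, 1, 1])[:2]
        sigma2 = float(rng.uniform(0.5, 2.0))
        betas = rng.standard_normal(2)
        model = VarCompModel(y, X, kernels)
        V = f[0] * kernels[0][1] + f[1] * kernels[1][1] + (1 - f.sum()) * np.eye(n)
        expected = dense_loglik(y, X, betas, sigma2 * V)
        assert loglikelihood(model, f, sigma2, betas) == pytest.approx(expected, abs=1e-9)

    def test_location_invariance_with_intercept(self):
        rng = np.random.default_rng(3)
        n = 8
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        K = random_psd(rng, n)
        model1 = VarCompModel(y, X, [("k", K)])
        model2 = VarCompModel(y + 5.0, X, [("k", K)])
        ll1 = loglikelihood(model1, [0.3], 1.2, [0.1])
        ll2 = loglikelihood(model2, [0.3], 1.2, [5.1])
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_invalid_params_rejected(self):
        model = VarCompModel(np.zeros(4), np.ones((4, 1)),
                             [("k", np.eye(4))])
        with pytest.raises(ValueError):
            loglikelihood(model, [1.5], 1.0, [0.0])
        with pytest.raises(ValueError):
            loglikelihood(model, [0.5], -1.0, [0.0])


@pytest.fixture(scope="module")
def family_data():
    cfg = desk_preset(seed=23, n_families=30, trait_h_r2=0.4)
    ped = simulate_pedigree(cfg)
    phi2 = additive_matrix(kinship_matrix(ped))
    pheno, _ = simulate_trait(ped, {}, cfg)
    y = pheno["trait"].to_numpy(float)
    X = _design(pheno, ("sex", "age"))
    return ped, phi2, y, X


class TestFitML:
    def test_deterministic_refits(self, family_data):
        _ped, phi2, y, X = family_data
        f1 = fit_ml(VarCompModel(y, X, [("polygenic", phi2)]))
        f2 = fit_ml(VarCompModel(y, X, [("polygenic", phi2)]))
        assert f1.loglik == f2.loglik
        assert f1.fractions == f2.fractions

    def test_scale_equivariance(self, family_data):
        _ped, phi2, y, X = family_data
        K = random_psd(np.random.default_rng(1), y.size)
        n0, f0 = fit_null_and_full(y, X, phi2, K)
        n1, f1 = fit_null_and_full(3.0 * y, X, phi2, K)
        assert f1.sigma2_total == pytest.approx(9.0 * f0.sigma2_total, rel=1e-6)
        for name in ("polygenic", "methylation"):
            assert f1.fraction(name) == pytest.approx(f0.fraction(name), abs=1e-6)
        lrt0 = 2 * (f0.loglik - n0.loglik)
        lrt1 = 2 * (f1.loglik - n1.loglik)
        assert lrt1 == pytest.approx(lrt0, abs=1e-6)

    def test_fractions_partition_unit_variance(self, family_data):
        _ped, phi2, y, X = family_data
        K = random_psd(np.random.default_rng(2), y.size)
        fit = fit_ml(VarCompModel(y, X, [("polygenic", phi2), ("methylation", K)]))
        total = sum(fit.fractions.values()) + fit.e2
        assert total == pytest.approx(1.0, abs=1e-6)
        assert all(0.0 <= v <= 1.0 for v in fit.fractions.values())
        assert fit.sigma2_total > 0

    def test_null_truth_on_unrelated_samples_estimates_near_zero(self):
        # founders only: 2*Phi = I, heritability unidentifiable from kinship,
        # and the fitted polygenic fraction must collapse to the boundary
        from methvc.pedigree import Individual, Pedigree

        rng = np.random.default_rng(5)
        n = 300
        ped = Pedigree([Individual(f"I{i}") for i in range(n)])
        phi2 = additive_matrix(kinship_matrix(ped))
        hits = 0
        reps = 50
        for _ in range(reps):
            y = rng.standard_normal(n)
            fit = fit_ml(VarCompModel(y, np.ones((n, 1)), [("polygenic", phi2)]))
            hits += fit.fraction("polygenic") <= 0.1
        assert hits >= 0.9 * reps

    def test_rank_deficient_design_rejected(self, family_data):
        _ped, phi2, y, X = family_data
        Xbad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            VarCompModel(y, Xbad, [("polygenic", phi2)])


class TestNullFull:
    def test_nesting_holds_for_every_fit(self, family_data):
        _ped, phi2, y, X = family_data
        rng = np.random.default_rng(9)
        for _ in range(5):
            K = random_psd(rng, y.size)
            null_fit, full_fit = fit_null_and_full(y, X, phi2, K)
            assert full_fit.loglik >= null_fit.loglik - 1e-6
            assert 2 * (full_fit.loglik - null_fit.loglik) >= 0.0

    def test_aliased_kernel_degenerates_to_null(self, family_data):
        _ped, phi2, y, X = family_data
        null_fit, full_fit = fit_null_and_full(y, X, phi2, phi2)
        assert full_fit.loglik == pytest.approx(null_fit.loglik, abs=1e-6)

    def test_power_against_true_methylation_component(self):
        from methvc.experiments import null_lrt_calibration  # noqa: F401  (shared setup style)
        from methvc.kernel import build_kernel

        cfg = desk_preset(seed=31, n_families=40, trait_h_r2=0.3,
                          trait_h_meth2=0.3, causal_genes=("G",))
        ped = simulate_pedigree(cfg)
        phi2 = additive_matrix(kinship_matrix(ped))
        rng = np.random.default_rng(31)
        lrts = []
        for _ in range(30):
            Z = rng.standard_normal((len(ped), 12))
            Z = (Z - Z.mean(0)) / Z.std(0, ddof=1)
            kern = build_kernel(Z, "G", ped.ids)
            pheno, _ = simulate_trait(ped, {"G": kern}, cfg, rng=rng)
            y = pheno["trait"].to_numpy(float)
            X = _design(pheno, ("sex", "age"))
            nf, ff = fit_null_and_full(y, X, phi2, kern.K)
            lrts.append(2 * (ff.loglik - nf.loglik))
        from scipy.stats import chi2

        assert np.median(lrts) > chi2.ppf(0.5, df=1)
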