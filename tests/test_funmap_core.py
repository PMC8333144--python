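import numpy as np
import pytest

from conftest import make_phenos, sad_noise
from fppfm.curve_basis import LOPBasis, legendre_value_sum
from fppfm.funmap_core import (
    FitOptions,
    MarkerSkipped,
    fit_marker,
    joint_log_likelihood,
    layout_from_series,
    mean_vector,
    select_order_aic,
)
from fppfm.sad_covariance import SADParams
from fppfm.simulation_study import SimConfig, simulate_matrices

STAGES = ["pre", "dry", "wet"]


def sim_phenos(seed, n=60, h2=0.10, correlated=True):
    cfg = SimConfig(n_individuals=n, n_markers=10, heritability=h2,
                    correlated=correlated)
    Y, codes, truth = simulate_matrices(cfg, seed)
    return make_phenos(Y, STAGES, 10), codes, truth, cfg


class TestMeanVector:
    def test_constant_curve(self):
        basis = LOPBasis(0, np.arange(5.0))
        assert np.allclose(mean_vector([[3.2]], [basis]), 3.2)

    def test_linear_is_tau(self):
        basis = LOPBasis(1, np.array([0.0, 15.0, 30.0]))
        assert np.allclose(mean_vector([[0.0, 1.0]], [basis]), [-1.0, 0.0, 1.0])

    def test_matches_factorial_sum_oracle(self, rng):
        """Design-matrix evaluation equals the closed-form polynomial sum."""
        times = np.linspace(0.0, 12.0, 9)
        basis = LOPBasis(4, times)
        v = rng.standard_normal(5)
        direct = np.array(
            [sum(v[k] * legendre_value_sum(k, tau) for k in range(5)) for tau in basis.tau]
        )
        assert np.allclose(mean_vector([v], [basis]), direct, atol=1e-10)

    def test_dimension_mismatch(self):
        basis = LOPBasis(2, np.arange(4.0))
        with pytest.raises(ValueError):
            basis.evaluate([1.0, 2.0])


class TestJointLogLikelihood:
    def test_density_at_mean_identity_covariance(self):
        T = 6
        mu = np.linspace(0, 1, T)
        phenos = make_phenos(mu[None, :], ["s1"], T)
        layout = layout_from_series(phenos, 1)
        ll = joint_log_likelihood(
            mu[None, :], np.array([0.0]), {0.0: mu},
            SADParams(phi2=1.0, rho=0.0), layout,
        )
        assert ll == pytest.approx(-T / 2 * np.log(2 * np.pi))

    def test_rho_zero_equals_univariate_product(self, rng):
        from scipy.stats import norm

        T, n = 8, 4
        Y = rng.standard_normal((n, T)) * 1.4 + 2.0
        mu = np.full(T, 2.0)
        phenos = make_phenos(Y, ["s1"], T)
        layout = layout_from_series(phenos, 1)
        params = SADParams(phi2=1.9, rho=0.0)
        ll = joint_log_likelihood(Y, np.zeros(n), {0.0: mu}, params, layout)
        oracle = norm.logpdf(Y, loc=2.0, scale=np.sqrt(1.9)).sum()
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_doubling_residuals_decreases_loglik(self, rng):
        T = 10
        mu = np.zeros(T)
        resid = rng.standard_normal((3, T))
        phenos = make_phenos(resid, ["s1"], T)
        layout = layout_from_series(phenos, 1)
        params = SADParams(phi2=1.0, rho=0.3)
        ll1 = joint_log_likelihood(resid, np.zeros(3), {0.0: mu}, params, layout)
        ll2 = joint_log_likelihood(2 * resid, np.zeros(3), {0.0: mu}, params, layout)
        assert ll2 < ll1


class TestFitMarker:
    def test_noiseless_recovery(self, rng):
        """With near-zero innovation variance the genotype coefficient vectors
        are recovered to high accuracy."""
        cfg = SimConfig(n_individuals=30, n_markers=5, heritability=0.10)
        from fppfm.simulation_study import template_curves

        mu_qq, mu_QQ, coefs = template_curves(cfg)
        geno = np.array([0.0, 2.0] * 15)
        Y = np.where((geno == 2.0)[:, None], mu_QQ, mu_qq) + rng.standard_normal(
            (30, 30)
        ) * 1e-5
        phenos = make_phenos(Y, list(cfg.stage_ids), 10)
        fit = fit_marker(phenos, geno, FitOptions(order=4))
        for si, sid in enumerate(cfg.stage_ids):
            assert np.allclose(
                fit.coefficients[("trait", sid, 0.0)], coefs[sid][:, 0], atol=1e-3
            )
            assert np.allclose(
                fit.coefficients[("trait", sid, 2.0)], coefs[sid][:, 1], atol=1e-3
            )
        assert fit.n_parameters == 2 * 1 * 3 * 5 + 2

    def test_profile_equals_nelder_mead(self):
        """The profiled 1-D optimiser reaches the same maximum as the joint
        simplex search over all parameters."""
        phenos, codes, truth, cfg = sim_phenos(7, n=30)
        opts_p = FitOptions(order=2)
        opts_nm = FitOptions(order=2, method="nelder-mead")
        g = codes[truth.causal_indices[0]]
        fp = fit_marker(phenos, g, opts_p)
        fnm = fit_marker(phenos, g, opts_nm)
        assert fp.loglik == pytest.approx(fnm.loglik, abs=1e-4)
        assert fp.sad.rho == pytest.approx(fnm.sad.rho, abs=1e-3)
        assert fp.sad.phi2 == pytest.approx(fnm.sad.phi2, rel=1e-3)

    def test_sad_parameter_recovery(self):
        """rho and phi2 estimates concentrate around the generating values."""
        reps = 40
        rhos, phis = [], []
        for r in range(reps):
            phenos, codes, truth, cfg = sim_phenos(100 + r, n=200, h2=0.10)
            fit = fit_marker(phenos, codes[truth.causal_indices[0]], FitOptions())
            rhos.append(fit.sad.rho)
            phis.append(fit.sad.phi2)
            if r == 0:
                phi2_true = truth.phi2
        rho_err = np.mean(rhos) - 0.6
        assert abs(rho_err) < 3 * np.std(rhos) / np.sqrt(reps) + 0.01
        assert abs(np.mean(phis) - phi2_true) / phi2_true < 0.05

    def test_small_group_skipped(self):
        phenos, codes, truth, cfg = sim_phenos(3, n=20)
        geno = np.zeros(20)
        geno[0] = 2.0
        with pytest.raises(MarkerSkipped):
            fit_marker(phenos, geno, FitOptions())

    def test_single_class_equals_null_model(self):
        """J=1 full fit is exactly the pooled no-QTL null fit."""
        phenos, codes, truth, cfg = sim_phenos(11, n=24)
        g_all0 = np.zeros(24)
        full = fit_marker(phenos, g_all0, FitOptions())
        null = fit_marker(phenos, codes[0], FitOptions(constraint="genotype"))
        assert full.loglik == pytest.approx(null.loglik, abs=1e-6)

    def test_affine_equivariance(self):
        """y -> a y + b maps fitted curves to a mu + b and phi2 to a^2 phi2."""
        phenos, codes, truth, cfg = sim_phenos(13, n=40)
        g = codes[truth.causal_indices[0]]
        fit = fit_marker(phenos, g, FitOptions())
        a, b = 2.5, -3.0
        data2 = phenos.data.copy()
        data2["value"] = a * data2["value"] + b
        from fppfm.io_data import PhenotypeSeries

        fit2 = fit_marker(PhenotypeSeries(data2, phenos.stage_order), g, FitOptions())
        layout = layout_from_series(phenos, 4)
        for code in fit.genotypes:
            mu1 = fit.mean_curve(code, "trait", layout.bases)
            mu2 = fit2.mean_curve(code, "trait", layout.bases)
            assert np.allclose(mu2, a * mu1 + b, atol=1e-6)
        assert fit2.sad.phi2 == pytest.approx(a**2 * fit.sad.phi2, rel=1e-6)
        assert fit2.sad.rho == pytest.approx(fit.sad.rho, abs=1e-6)

    def test_nested_loglik_monotone_in_order(self):
        phenos, codes, truth, cfg = sim_phenos(17, n=40)
        g = codes[truth.causal_indices[0]]
        lls = [fit_marker(phenos, g, FitOptions(order=k)).loglik for k in range(5)]
        assert np.all(np.diff(lls) >= -1e-4)


class TestOrderSelection:
    def test_aic_formula(self):
        # AIC = -2 lnL + 2 dim: lnL = -100, dim = 10 -> 220
        assert -2 * (-100.0) + 2 * 10 == 220.0

    def test_selects_generating_order(self):
        """Data from an order-2 curve with low noise selects k = 2 in most
        replicates (AIC overshoots with known small probability, so the
        check is on the modal selection, never on undershoot)."""
        n, T = 400, 10
        basis = LOPBasis(2, np.arange(float(T)))
        mu0 = basis.evaluate([1.0, 0.5, -0.8])
        mu1 = basis.evaluate([1.4, 0.2, -0.5])
        geno = np.array([0.0, 2.0] * (n // 2))
        selections = []
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            Y = np.where((geno == 2.0)[:, None], mu1, mu0) + sad_noise(
                rng, n, T, 0.4, 0.05
            )
            phenos = make_phenos(Y, ["s1"], T)
            sel = select_order_aic(phenos, geno, range(0, 5), FitOptions())
            assert sel.aics[sel.orders.index(sel.selected)] == min(sel.aics)
            assert sel.selected >= 2  # never underfits at this noise level
            selections.append(sel.selected)
        assert selections.count(2) >= 6
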