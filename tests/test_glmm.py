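"""GLMM fitter: polynomial basis, degenerate cases, quadrature oracles,
truncated negative binomial, order selection and the bootstrap LRT."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import integrate, stats

import twinfert as tf
from twinfert.glmm import (MODEL_SPECS, ModelSpec, TruncatedNegBinom,
                           _agq_loglik, _FAMILIES, build_poly_basis,
                           fit_glmm, lrt_parametric_bootstrap,
                           select_poly_order)


def _binom_df(n=400, seed=0, n_groups=4, beta=(-2.0, 0.15), sigma=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "births_total": rng.integers(1, 15, n).astype(float),
        "population_id": rng.choice([f"p{i}" for i in range(n_groups)], n),
    })
    u = rng.normal(0, sigma, n_groups)
    codes = pd.factorize(df["population_id"])[0]
    eta = beta[0] + beta[1] * df["births_total"] + u[codes]
    df["twinner"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return df


SPEC2 = ModelSpec("m2", "twinner", "binomial", ("births_total",))


class TestPolyBasis:
    def test_order_zero_is_empty(self):
        M, names, _ = build_poly_basis(np.arange(5.0), np.arange(5.0), 0)
        assert M.shape == (5, 0) and names == []

    @pytest.mark.parametrize("order,ncols", [(1, 2), (2, 5), (3, 9), (6, 27)])
    def test_column_count(self, order, ncols):
        a = np.linspace(200, 500, 40)
        p = np.arange(40) % 7 + 1.0
        M, names, _ = build_poly_basis(a, p, order)
        assert M.shape[1] == ncols == len(names)

    def test_order_out_of_range(self):
        with pytest.raises(ValueError, match="order"):
            build_poly_basis(np.arange(4.0), np.arange(4.0), 7)

    def test_orthogonalised_fit_invariant(self):
        """Fitted values must not depend on the basis parameterisation."""
        rng = np.random.default_rng(5)
        n = 300
        df = pd.DataFrame({
            "age_months": rng.uniform(200, 550, n),
            "parity": rng.integers(1, 10, n).astype(float),
            "population_id": rng.choice(list("AB"), n),
        })
        eta = -3.5 + 0.004 * (df["age_months"] - 360)
        df["twin"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        spec = ModelSpec("t", "twin", "binomial", ("poly",), 2)
        raw = fit_glmm(spec, df, fix_sigma2={"population_id": 0})
        ortho = fit_glmm(spec, df, fix_sigma2={"population_id": 0},
                         orthogonalize=True)
        mu_raw = raw.family().mean(raw.linpred(df, random=()))
        mu_ortho = ortho.family().mean(ortho.linpred(df, random=()))
        assert np.allclose(mu_raw, mu_ortho, atol=1e-6)
        assert raw.loglik == pytest.approx(ortho.loglik, abs=1e-6)


class TestDegenerateAndOracles:
    def test_sigma2_zero_matches_glm(self):
        df = _binom_df()
        ours = fit_glmm(SPEC2, df, fix_sigma2={"population_id": 0})
        X = sm.add_constant(df["births_total"])
        glm = sm.GLM(df["twinner"], X, family=sm.families.Binomial()).fit()
        assert np.allclose(ours.beta.to_numpy(), glm.params.to_numpy(),
                           atol=1e-6)
        assert ours.loglik == pytest.approx(glm.llf, abs=1e-6)
        assert ours.sigma2["population_id"] == 0.0

    def test_agq_matches_brute_force_integration(self):
        """Adaptive GH marginal log-likelihood vs direct numerical
        integration on a tiny 3-group instance, to 1e-6."""
        rng = np.random.default_rng(1)
        g = np.repeat(np.arange(3), 4)
        x = rng.normal(size=12)
        u = rng.normal(0, 0.8, 3)
        y = (rng.random(12) < 1 / (1 + np.exp(-(-0.3 + 0.6 * x + u[g])))
             ).astype(float)
        fam = _FAMILIES["binomial"]
        X = np.column_stack([np.ones(12), x])
        beta, s2 = np.array([-0.2, 0.5]), 0.5
        ll_agq = _agq_loglik(y, np.ones(12), X, g, 3, fam, beta, s2, None,
                             n_nodes=30)
        eta0 = X @ beta
        ll_quad = 0.0
        for gg in range(3):
            m = g == gg
            f = lambda u_, m=m: np.exp(
                np.sum(fam.loglik(y[m], eta0[m] + u_, np.ones(m.sum()), None))
            ) * stats.norm.pdf(u_, 0, np.sqrt(s2))
            v, _ = integrate.quad(f, -10, 10, limit=200)
            ll_quad += np.log(v)
        assert ll_agq == pytest.approx(ll_quad, abs=1e-6)

    def test_laplace_close_to_agq_with_rich_groups(self):
        """With many observations per group the Laplace approximation is
        close to the (near-exact) AGQ likelihood."""
        df = _binom_df(n=1200, seed=7, n_groups=5, sigma=0.6)
        lap = fit_glmm(SPEC2, df)
        agq = fit_glmm(SPEC2, df, method="agq")
        assert lap.loglik == pytest.approx(agq.loglik, abs=0.05)
        assert np.allclose(lap.beta.to_numpy(), agq.beta.to_numpy(), atol=0.02)

    def test_parameter_recovery_binomial(self):
        """True coefficients inside 4-SE Wald bands on one synthetic fit."""
        df = _binom_df(n=2000, seed=9, n_groups=12, sigma=0.5)
        fit = fit_glmm(SPEC2, df)
        z = (fit.beta.to_numpy() - np.array([-2.0, 0.15])) / fit.se_beta.to_numpy()
        assert np.all(np.abs(z) < 4)
        assert 0.02 < fit.sigma2["population_id"] < 2.0


class TestTruncatedNegBin:
    def test_pmf_zero_and_normalisation(self):
        d = TruncatedNegBinom(3.0, 1.5)
        assert d.pmf(0) == 0.0
        ks = np.arange(0, 500)
        assert d.pmf(ks).sum() == pytest.approx(1.0, abs=1e-10)

    def test_sampler_mean_matches_closed_form(self):
        d = TruncatedNegBinom(4.0, 2.0)
        rng = np.random.default_rng(3)
        samp = d.rvs(rng, size=100_000)
        se = samp.std() / np.sqrt(len(samp))
        assert samp.min() >= 1
        assert abs(samp.mean() - d.mean()) < 4 * se

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            TruncatedNegBinom(-1.0, 2.0)
        with pytest.raises(ValueError):
            TruncatedNegBinom(2.0, 0.0)

    def test_truncated_fit_recovers_parameters(self):
        """Zero-free counts: the truncated-NB GLM recovers (mu, shape)."""
        rng = np.random.default_rng(4)
        mu, shape, n = 5.0, 3.0, 3000
        y = TruncatedNegBinom(mu, shape).rvs(rng, size=n)
        df = pd.DataFrame({"births_total": y.astype(float),
                           "twinner": np.zeros(n),
                           "population_id": rng.choice(list("AB"), n)})
        spec = MODEL_SPECS[1].drop(term="twinner")
        fit = fit_glmm(spec, df, fix_sigma2={"population_id": 0})
        assert np.exp(fit.beta["(Intercept)"]) == pytest.approx(mu, rel=0.05)
        assert fit.shape == pytest.approx(shape, rel=0.25)


class TestOrderSelection:
    def test_trace_has_all_orders_and_picks_small_for_linear_truth(self):
        rng = np.random.default_rng(6)
        n = 1500
        df = pd.DataFrame({
            "age_months": rng.uniform(200, 550, n),
            "parity": rng.integers(1, 10, n).astype(float),
            "population_id": rng.choice(list("ABCD"), n),
        })
        eta = 0.5 - 0.006 * (df["age_months"] - 360)  # linear age only
        df["PP"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        spec = ModelSpec("pp", "PP", "binomial", ("poly",), None)
        best, trace = select_poly_order(spec, df, orders=range(4))
        assert sorted(trace) == [0, 1, 2, 3]
        assert best in (1, 2)
        assert trace[best] <= trace[0]  # linear truth beats intercept-only


class TestBootstrapLRT:
    def test_identical_specs_give_null_result(self, dataset):
        fit = fit_glmm(SPEC2, dataset.mothers)
        p, lr, lrs = lrt_parametric_bootstrap(fit, fit, dataset.mothers,
                                              n_boot=9, seed=1)
        assert lr == pytest.approx(0.0, abs=1e-9)
        assert p == 1.0

    def test_detects_strong_effect(self):
        df = _binom_df(n=800, seed=8, beta=(-2.0, 0.5))
        null = fit_glmm(SPEC2.drop(term="births_total"), df)
        alt = fit_glmm(SPEC2, df)
        p, lr, _ = lrt_parametric_bootstrap(null, alt, df, n_boot=19, seed=2)
        assert lr > 10
        assert p == pytest.approx(1 / 20, abs=1e-12)


class TestSuiteStructure:
    def test_nested_model_relations(self):
        assert "twin" not in MODEL_SPECS[8].terms
        assert "twin" not in MODEL_SPECS[9].terms
        assert "poly" not in MODEL_SPECS[10].terms
        assert MODEL_SPECS[11].random_effects == ("population_id",)
        assert "poly" in MODEL_SPECS[12].terms
        assert MODEL_SPECS[12].random_effects == ("population_id",)

    def test_suite_fits_and_aic_accounting(self, suite):
        for k in range(1, 13):
            f = suite[k]
            assert f.converged, f"model {k} did not converge"
            k_params = len(f.beta) + sum(v > 0 for v in f.sigma2.values()) \
                + (1 if f.shape is not None else 0)
            assert f.aic == pytest.approx(-2 * f.loglik + 2 * k_params)
        # model 5 uses only rows with a following birth
        assert suite[5].n_obs < suite[4].n_obs
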