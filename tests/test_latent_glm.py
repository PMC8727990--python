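"""Latent-genotype GLM: hand oracles, classical reductions, EM properties."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

from latentgwas import (
    Design,
    GenotypePosterior,
    GenotypePrior,
    Theta,
    fisher_se,
    fit_dosage,
    fit_hybrid,
    fit_latent,
    loglik,
    posterior,
    prime_from_dosage,
    score_test,
    simulate_genotype_likelihoods,
)
from latentgwas.latent_glm import NonEstimableSiteError, observed_information

from conftest import degenerate_posterior, simulated_design


# ---------------------------------------------------------------------------
# log-likelihood oracles
# ---------------------------------------------------------------------------

class TestLoglik:
    def _toy(self):
        y = np.array([0.3, -1.2, 2.0])
        probs = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        Z = np.array([[0.5], [-1.0], [0.2]])
        return y, probs, Z

    def test_matches_hand_summed_mixture_gaussian(self):
        y, probs, Z = self._toy()
        th = Theta(alpha=0.1, beta=0.4, gamma=np.array([-0.3]), sigma2=1.3)
        expected = 0.0  # independent double-loop oracle
        for i in range(3):
            acc = 0.0
            for g in range(3):
                eta = th.alpha + th.beta * g + Z[i, 0] * th.gamma[0]
                dens = np.exp(-0.5 * (y[i] - eta) ** 2 / th.sigma2) / np.sqrt(
                    2 * np.pi * th.sigma2
                )
                acc += probs[i, g] * dens
            expected += np.log(acc)
        d = Design(y=y, post=GenotypePosterior(probs=probs), Z=Z)
        assert loglik(th, d, "gaussian") == pytest.approx(expected, abs=1e-10)

    def test_matches_hand_summed_mixture_binomial(self):
        y = np.array([1.0, 0.0, 1.0])
        probs = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.1, 0.1, 0.8]])
        th = Theta(alpha=-0.2, beta=0.7)
        expected = 0.0
        for i in range(3):
            acc = 0.0
            for g in range(3):
                mu = 1 / (1 + np.exp(-(th.alpha + th.beta * g)))
                acc += probs[i, g] * (mu if y[i] == 1 else 1 - mu)
            expected += np.log(acc)
        d = Design(y=y, post=GenotypePosterior(probs=probs))
        assert loglik(th, d, "binomial") == pytest.approx(expected, abs=1e-10)

    def test_zero_beta_ignores_genotype_uncertainty(self):
        y, probs, Z = self._toy()
        th = Theta(alpha=0.2, beta=0.0, gamma=np.array([0.1]), sigma2=1.0)
        d1 = Design(y=y, post=GenotypePosterior(probs=probs), Z=Z)
        d2 = Design(y=y, post=degenerate_posterior([0, 1, 2]), Z=Z)
        assert loglik(th, d1, "gaussian") == pytest.approx(
            loglik(th, d2, "gaussian"), abs=1e-12
        )

    def test_degenerate_posterior_collapses_to_normal_regression(self):
        y, _, Z = self._toy()
        g = np.array([0, 2, 1])
        th = Theta(alpha=0.1, beta=0.4, gamma=np.array([-0.3]), sigma2=0.9)
        d = Design(y=y, post=degenerate_posterior(g), Z=Z)
        eta = th.alpha + th.beta * g + Z[:, 0] * th.gamma[0]
        expected = stats.norm.logpdf(y, eta, np.sqrt(th.sigma2)).sum()
        assert loglik(th, d, "gaussian") == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# reductions with certain genotypes
# ---------------------------------------------------------------------------

class TestCertainGenotypeReduction:
    def test_gaussian_matches_ols(self, rng):
        n = 60
        g = rng.binomial(2, 0.4, n)
        Z = rng.normal(size=(n, 2))
        y = 0.5 * g + Z @ [0.3, -0.2] + rng.normal(size=n)
        d = Design(y=y, post=degenerate_posterior(g), Z=Z)
        fit = fit_latent(d, "gaussian")
        X = np.column_stack([np.ones(n), g, Z])
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.theta.coef_vector(), ols.params, atol=1e-8)
        # SEs use the MLE sigma^2 (divide by n), OLS uses n - p
        s2_mle = ols.ssr / n
        se_expected = np.sqrt(np.diag(s2_mle * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(fit.se, se_expected, rtol=1e-6)
        assert fit.iterations <= 2
        # dosage model is identical here
        fd = fit_dosage(d, "gaussian")
        np.testing.assert_allclose(fd.theta.coef_vector(), ols.params, atol=1e-10)
        np.testing.assert_allclose(fd.se, se_expected, rtol=1e-6)
        assert fd.pvalue == pytest.approx(fit.pvalue, rel=1e-4)

    def test_binomial_matches_logit(self, rng):
        n = 120
        g = rng.binomial(2, 0.4, n)
        Z = rng.normal(size=(n, 1))
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.6 * g - 0.4 * Z[:, 0])))).astype(float)
        d = Design(y=y, post=degenerate_posterior(g), Z=Z)
        fit = fit_latent(d, "binomial")
        X = np.column_stack([np.ones(n), g, Z])
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.theta.coef_vector(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_poisson_matches_glm(self, rng):
        n = 150
        g = rng.binomial(2, 0.4, n)
        y = rng.poisson(np.exp(0.2 + 0.3 * g)).astype(float)
        d = Design(y=y, post=degenerate_posterior(g))
        fit = fit_latent(d, "poisson")
        X = np.column_stack([np.ones(n), g])
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.theta.coef_vector(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_score_test_reduces_to_classical(self, rng):
        n = 80
        g = rng.binomial(2, 0.4, n).astype(float)
        y = rng.normal(size=n)
        d = Design(y=y, post=degenerate_posterior(g.astype(int)))
        stat, p = score_test(d, "gaussian")
        # classical score test for adding g to an intercept-only normal model
        r = y - y.mean()
        s2 = r @ r / n
        U = r @ g / s2
        gc = g - g.mean()
        stat_ref = U**2 * s2 / (gc @ gc)
        assert stat == pytest.approx(stat_ref, rel=1e-6)
        assert p == pytest.approx(stats.chi2.sf(stat_ref, 1), rel=1e-6)


# ---------------------------------------------------------------------------
# EM against direct numerical maximization
# ---------------------------------------------------------------------------

class TestEmOracle:
    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_em_matches_direct_maximization(self, family, rng):
        """EM optimum equals a quasi-Newton maximization of the mixture loglik
        on 10+10 random small instances."""
        for _ in range(10):
            d, _ = simulated_design(
                rng, n=40, f=rng.uniform(0.2, 0.6), beta=rng.normal(0, 0.6),
                depth=1.5, family=family,
            )
            try:
                # tight EM tolerance so beta-hat is pinned well below the
                # 1e-4 comparison level
                fit = fit_latent(d, family, tol=1e-11, max_iter=500)
            except NonEstimableSiteError:
                continue

            if family == "gaussian":
                def neg(v):
                    th = Theta(alpha=v[0], beta=v[1], sigma2=np.exp(v[2]))
                    return -loglik(th, d, family)
                x0 = [fit.theta.alpha + 0.3, fit.theta.beta - 0.3,
                      np.log(fit.theta.sigma2) + 0.2]
            else:
                def neg(v):
                    return -loglik(Theta(alpha=v[0], beta=v[1]), d, family)
                x0 = [fit.theta.alpha + 0.3, fit.theta.beta - 0.3]
            res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                    options=dict(xatol=1e-8, fatol=1e-12,
                                                 maxiter=4000))
            assert abs(fit.theta.beta - res.x[1]) < 1e-4
            assert -res.fun <= fit.loglik + 1e-6

    def test_loglik_path_monotone_every_family(self, rng):
        for family in ["gaussian", "binomial", "poisson"]:
            d, _ = simulated_design(rng, n=150, beta=0.5, depth=1.0, family=family)
            fit = fit_latent(d, family)
            assert np.all(np.diff(fit.loglik_path) >= -1e-8)
            assert fit.converged

    def test_six_individual_grid_search(self):
        """On a tiny fixed cohort the EM coefficients sit at the grid argmax."""
        y = np.array([0.1, 1.4, -0.6, 2.2, 0.9, -0.2])
        probs = np.array([
            [0.8, 0.15, 0.05], [0.1, 0.6, 0.3], [0.7, 0.25, 0.05],
            [0.05, 0.35, 0.6], [0.3, 0.5, 0.2], [0.6, 0.3, 0.1],
        ])
        d = Design(y=y, post=GenotypePosterior(probs=probs))
        fit = fit_latent(d, "gaussian")
        alphas = np.linspace(fit.theta.alpha - 0.5, fit.theta.alpha + 0.5, 81)
        betas = np.linspace(fit.theta.beta - 0.5, fit.theta.beta + 0.5, 81)
        best, arg = -np.inf, None
        for a in alphas:
            for b in betas:
                ll = loglik(Theta(alpha=a, beta=b, sigma2=fit.theta.sigma2),
                            d, "gaussian")
                if ll > best:
                    best, arg = ll, (a, b)
        # grid resolution 0.0125; the EM optimum must be the central cell
        assert abs(arg[0] - fit.theta.alpha) <= 0.0125 / 2 + 1e-12
        assert abs(arg[1] - fit.theta.beta) <= 0.0125 / 2 + 1e-12


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

class TestFisherSe:
    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_matches_dense_numerical_hessian(self, family, rng):
        d, _ = simulated_design(rng, n=60, beta=0.6, depth=1.5, family=family,
                                n_cov=1, gamma=np.array([0.3]))
        fit = fit_latent(d, family)
        th = fit.theta
        if family == "gaussian":
            v0 = np.append(th.coef_vector(), th.sigma2)
            def f(v):
                return loglik(Theta(alpha=v[0], beta=v[1], gamma=v[2:3],
                                    sigma2=v[3]), d, family)
        else:
            v0 = th.coef_vector()
            def f(v):
                return loglik(Theta(alpha=v[0], beta=v[1], gamma=v[2:3]), d, family)
        p = v0.size
        H = np.empty((p, p))
        h = 1e-4
        for i in range(p):
            for j in range(p):
                vpp, vpm, vmp, vmm = (v0.copy() for _ in range(4))
                vpp[i] += h; vpp[j] += h
                vpm[i] += h; vpm[j] -= h
                vmp[i] -= h; vmp[j] += h
                vmm[i] -= h; vmm[j] -= h
                H[i, j] = (f(vpp) - f(vpm) - f(vmp) + f(vmm)) / (4 * h * h)
        se_num = np.sqrt(np.diag(np.linalg.inv(-H))[: 3])
        np.testing.assert_allclose(fit.se, se_num, rtol=1e-4)

    def test_se_calibrated_against_replicate_scatter(self, rng):
        """Mean reported SE within 10% of the empirical SD of beta-hat."""
        betas, ses = [], []
        for _ in range(400):
            d, _ = simulated_design(rng, n=400, f=0.45, beta=0.3, depth=1.0)
            fit = fit_latent(d, "gaussian")
            betas.append(fit.theta.beta)
            ses.append(fit.se_beta)
        ratio = np.mean(ses) / np.std(betas, ddof=1)
        assert 0.9 < ratio < 1.1

    def test_degenerate_gaussian_matches_closed_form(self, rng):
        n = 50
        g = rng.binomial(2, 0.5, n)
        y = 0.3 * g + rng.normal(size=n)
        d = Design(y=y, post=degenerate_posterior(g))
        fit = fit_latent(d, "gaussian")
        se_b, se = fisher_se(fit.theta, d, "gaussian")
        X = np.column_stack([np.ones(n), g])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = resid @ resid / n
        expected = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(se, expected, rtol=1e-6)
        assert se_b == pytest.approx(expected[1], rel=1e-6)


# ---------------------------------------------------------------------------
# dosage model, priming, hybrid, score behaviour
# ---------------------------------------------------------------------------

class TestDosageModel:
    def test_closed_form_simple_regression_slope(self):
        y = np.array([0.2, 1.1, 0.9, 2.3, 1.7])
        probs = np.array([
            [0.9, 0.1, 0.0], [0.2, 0.6, 0.2], [0.5, 0.4, 0.1],
            [0.0, 0.3, 0.7], [0.1, 0.5, 0.4],
        ])
        d = Design(y=y, post=GenotypePosterior(probs=probs))
        fit = fit_dosage(d, "gaussian")
        dos = d.post.dosage
        slope = np.cov(dos, y, ddof=1)[0, 1] / np.var(dos, ddof=1)
        assert fit.theta.beta == pytest.approx(slope, rel=1e-10)

    def test_invariant_to_likelihood_rescaling(self, rng):
        from latentgwas import GenotypeLikelihoods

        g = rng.binomial(2, 0.4, 50)
        gl = simulate_genotype_likelihoods(g, 2.0, 0.01, rng)
        y = 0.4 * g + rng.normal(size=50)
        scale = rng.uniform(0.5, 2.0, size=(50, 1))
        gl2 = GenotypeLikelihoods(log_gl=gl.log_gl + np.log(scale), depth=gl.depth)
        prior = GenotypePrior.sample_af(0.4)
        f1 = fit_dosage(Design(y=y, post=posterior(gl, prior)), "gaussian")
        f2 = fit_dosage(Design(y=y, post=posterior(gl2, prior)), "gaussian")
        assert f1.theta.beta == pytest.approx(f2.theta.beta, abs=1e-12)


class TestPriming:
    def test_degenerate_posterior_primes_to_final_fit(self, rng):
        n = 60
        g = rng.binomial(2, 0.4, n)
        y = 0.5 * g + rng.normal(size=n)
        d = Design(y=y, post=degenerate_posterior(g))
        th0 = prime_from_dosage(d, "gaussian")
        fit = fit_latent(d, "gaussian")
        np.testing.assert_allclose(th0.coef_vector(), fit.theta.coef_vector(),
                                   atol=1e-10)
        assert fit.iterations <= 2

    def test_priming_preserves_optimum_and_cuts_iterations(self, rng):
        n_sites, wins, deltas = 50, 0, []
        for _ in range(n_sites):
            d, _ = simulated_design(rng, n=300, f=0.45, beta=0.3, depth=1.0)
            primed = fit_latent(d, "gaussian", prime=True, tol=1e-10)
            cold = fit_latent(d, "gaussian", prime=False, tol=1e-10)
            deltas.append(abs(primed.theta.beta - cold.theta.beta))
            wins += primed.iterations <= cold.iterations
        assert max(deltas) < 1e-5
        assert wins >= 0.9 * n_sites


class TestScoreAndHybrid:
    def test_no_dosage_variance_gives_null_result(self):
        post = GenotypePosterior(probs=np.tile([0.25, 0.5, 0.25], (20, 1)))
        d = Design(y=np.random.default_rng(0).normal(size=20), post=post)
        stat, p = score_test(d, "gaussian")
        assert stat == 0.0 and p == 1.0
        with pytest.raises(NonEstimableSiteError):
            fit_latent(d, "gaussian")

    def test_hybrid_branches(self, rng):
        # strong effect: EM branch, identical to the full latent fit
        d, _ = simulated_design(rng, n=400, beta=1.0, depth=4.0)
        hyb = fit_hybrid(d, "gaussian")
        full = fit_latent(d, "gaussian")
        assert hyb.branch == "em"
        assert hyb.theta.beta == pytest.approx(full.theta.beta, abs=1e-12)
        assert hyb.pvalue == pytest.approx(full.pvalue, abs=1e-15)
        # null effect with a lenient-but-not-passed screen: score branch
        d0, _ = simulated_design(rng, n=400, beta=0.0, depth=1.0)
        hyb0 = fit_hybrid(d0, "gaussian", screen_alpha=1e-6)
        assert hyb0.branch == "score"
        assert np.isnan(hyb0.theta.beta)
        # screen_alpha=1: always the EM branch
        hyb1 = fit_hybrid(d0, "gaussian", screen_alpha=1.0)
        assert hyb1.branch == "em"

    def test_hybrid_equals_latent_wherever_screen_passes(self, rng):
        n_em = 0
        for _ in range(40):
            d, _ = simulated_design(rng, n=150, f=0.4,
                                    beta=rng.normal(0, 0.4), depth=1.5)
            try:
                hyb = fit_hybrid(d, "gaussian", screen_alpha=0.1)
            except NonEstimableSiteError:
                continue
            if hyb.branch == "em":
                full = fit_latent(d, "gaussian")
                assert hyb.pvalue == pytest.approx(full.pvalue, abs=1e-15)
                assert hyb.theta.beta == pytest.approx(full.theta.beta, abs=1e-12)
                n_em += 1
            else:
                assert np.isnan(hyb.theta.beta) and hyb.pvalue >= 0.1
        assert n_em >= 3  # the sweep actually exercised both branches

    def test_pvalues_uniform_under_null(self, rng):
        """Wald and score p-values are uniform when beta=0 (KS at alpha=0.01)."""
        pw, ps = [], []
        for _ in range(600):
            d, _ = simulated_design(rng, n=150, f=0.3, beta=0.0, depth=1.0)
            try:
                pw.append(fit_latent(d, "gaussian").pvalue)
            except NonEstimableSiteError:
                continue
            ps.append(score_test(d, "gaussian")[1])
        assert stats.kstest(pw, "uniform").pvalue > 0.01
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGroupedWeights:
    def test_grouped_fits_match_expanded_rows(self):
        """Frequency-weighted fits on unique patterns equal per-individual fits."""
        y_binary = np.array([0.0, 0.0, 1.0, 1.0])
        # continuous pattern values for the gaussian check (4 distinct values
        # cannot be matched exactly by 3 genotype means, so sigma2 stays
        # bounded away from the mixture degeneracy)
        y_cont = np.array([0.2, -0.3, 1.1, 0.8])
        probs = np.array([
            [0.7, 0.25, 0.05], [0.3, 0.5, 0.2],
            [0.6, 0.3, 0.1], [0.1, 0.5, 0.4],
        ])
        w = np.array([30, 20, 25, 25])
        idx = np.repeat(np.arange(4), w)
        for family in ["gaussian", "binomial"]:
            y_pat = y_cont if family == "gaussian" else y_binary
            grouped = Design(y=y_pat, post=GenotypePosterior(probs=probs),
                             freq_weights=w.astype(float))
            expanded = Design(y=y_pat[idx], post=GenotypePosterior(probs=probs[idx]))
            fg = fit_latent(grouped, family)
            fe = fit_latent(expanded, family)
            np.testing.assert_allclose(fg.theta.coef_vector(),
                                       fe.theta.coef_vector(), atol=1e-8)
            assert fg.se_beta == pytest.approx(fe.se_beta, rel=1e-6)
            assert fg.loglik == pytest.approx(fe.loglik, rel=1e-10)
            sg, se_ = score_test(grouped, family), score_test(expanded, family)
            assert sg[0] == pytest.approx(se_[0], rel=1e-8)
            dg, de = fit_dosage(grouped, family), fit_dosage(expanded, family)
            assert dg.theta.beta == pytest.approx(de.theta.beta, abs=1e-10)
            assert dg.se_beta == pytest.approx(de.se_beta, rel=1e-8)


class TestValidation:
    def test_collinear_design_raises(self, rng):
        from latentgwas.glm import SingularFitError

        d, g = simulated_design(rng, n=50, beta=0.3, depth=2.0)
        Z = np.column_stack([np.ones(50), np.ones(50)])  # collinear with intercept
        bad = Design(y=d.y, post=d.post, Z=Z)
        with pytest.raises(SingularFitError):
            fit_latent(bad, "gaussian")

    def test_missing_values_rejected(self, rng):
        d, g = simulated_design(rng, n=10, beta=0.3, depth=2.0)
        y = d.y.copy()
        y[3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            Design(y=y, post=d.post)
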