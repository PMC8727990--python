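"""Association estimators for genotype-uncertain data.

The genotype at a tested site is never observed directly; instead each
individual carries a posterior distribution over g in {0, 1, 2}.  The latent
model marginalizes the GLM likelihood over that distribution,

    l(theta) = sum_i log sum_g p(y_i | G=g, z_i, theta) p(G=g | x_i),

with linear predictor eta_ig = alpha + beta*g + z_i' gamma, and maximizes it
by EM: the E-step computes genotype responsibilities, the M-step is a
weighted GLM on the 3N expanded rows.  EM is initialized from a regression on
the posterior-mean genotypes ("priming"), which typically cuts the iteration
count severalfold without changing the optimum.

Standard errors come from the observed Fisher information of the marginal
log-likelihood at the optimum (finite differences of the analytic gradient);
p-values are Wald against chi-square(1).  Alternatives: the plain dosage GLM
(:func:`fit_dosage`), a score test that needs no alternative-model fit
(:func:`score_test`), and a hybrid that screens with the score test and runs
EM only on promising sites (:func:`fit_hybrid`).

All fits accept optional frequency weights, so designs whose rows collapse
into repeated (y, posterior) patterns can be fitted on the unique patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .genoprob import GenotypePosterior
from .glm import Family, SingularFitError, fit_weighted_glm, get_family

__all__ = [
    "Design",
    "Theta",
    "LatentGlmFit",
    "loglik",
    "fit_latent",
    "fit_dosage",
    "prime_from_dosage",
    "fisher_se",
    "score_test",
    "fit_hybrid",
    "NonEstimableSiteError",
]

_G = np.array([0.0, 1.0, 2.0])
_DOSAGE_VAR_MIN = 1e-8


class NonEstimableSiteError(ValueError):
    """Posterior dosages carry (essentially) no variance; beta is not estimable."""


@dataclass
class Design:
    """Phenotype, covariates and genotype posterior for one tested site.

    Parameters
    ----------
    y : (N,) phenotype (real; 0/1 for binomial; counts for poisson)
    Z : (N, c) covariate matrix or None
    post : GenotypePosterior for the site
    freq_weights : optional (N,) positive weights; row i counts as
        freq_weights[i] identical individuals (grouped data).
    """

    y: np.ndarray
    post: GenotypePosterior
    Z: np.ndarray | None = None
    freq_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        n = self.y.shape[0]
        if self.Z is not None:
            self.Z = np.asarray(self.Z, dtype=float)
            if self.Z.ndim == 1:
                self.Z = self.Z[:, None]
            if self.Z.shape[0] != n:
                raise ValueError("Z rows must match y")
        if self.post.n_individuals != n:
            raise ValueError("posterior rows must match y")
        if self.freq_weights is not None:
            self.freq_weights = np.asarray(self.freq_weights, dtype=float)
            if np.any(self.freq_weights < 0):
                raise ValueError("freq_weights must be non-negative")
        if np.any(~np.isfinite(self.y)) or (
            self.Z is not None and np.any(~np.isfinite(self.Z))
        ):
            raise ValueError("missing values must be removed before fitting")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_covariates(self) -> int:
        return 0 if self.Z is None else self.Z.shape[1]

    @property
    def weights(self) -> np.ndarray:
        if self.freq_weights is None:
            return np.ones(self.n)
        return self.freq_weights

    def expanded_design(self) -> tuple[np.ndarray, np.ndarray]:
        """(3N, p) design with genotype column enumerated, and repeated y."""
        n, c = self.n, self.n_covariates
        X = np.empty((3 * n, 2 + c))
        X[:, 0] = 1.0
        X[:, 1] = np.tile(_G, n)
        if c:
            X[:, 2:] = np.repeat(self.Z, 3, axis=0)
        return X, np.repeat(self.y, 3)

    def dosage_design(self) -> np.ndarray:
        n, c = self.n, self.n_covariates
        X = np.empty((n, 2 + c))
        X[:, 0] = 1.0
        X[:, 1] = self.post.dosage
        if c:
            X[:, 2:] = self.Z
        return X


@dataclass
class Theta:
    """GLM parameters: intercept, genotype effect, covariate effects, scale."""

    alpha: float
    beta: float
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma2: float | None = None

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def coef_vector(self) -> np.ndarray:
        return np.concatenate([[self.alpha, self.beta], self.gamma])

    @classmethod
    def from_coef_vector(cls, v: np.ndarray, sigma2: float | None = None) -> "Theta":
        v = np.asarray(v, dtype=float)
        return cls(alpha=v[0], beta=v[1], gamma=v[2:], sigma2=sigma2)


@dataclass
class LatentGlmFit:
    """Result of an association fit at one site."""

    theta: Theta
    se_beta: float
    loglik: float
    iterations: int
    converged: bool
    pvalue: float
    method: str
    se: np.ndarray | None = None
    statistic: float | None = None
    branch: str | None = None
    loglik_path: np.ndarray | None = None  # per-EM-iteration marginal loglik


def _eta_matrix(theta: Theta, design: Design) -> np.ndarray:
    """(N, 3) linear predictor alpha + beta*g + Z gamma."""
    base = np.full(design.n, theta.alpha)
    if design.n_covariates:
        base = base + design.Z @ theta.gamma
    return base[:, None] + theta.beta * _G[None, :]


def _log_pdf_matrix(theta: Theta, design: Design, fam: Family) -> np.ndarray:
    eta = _eta_matrix(theta, design)
    return fam.log_pdf(design.y[:, None], eta, theta.sigma2)


def _log_post(design: Design) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(design.post.probs)


def loglik(theta: Theta, design: Design, family: str | Family = "gaussian") -> float:
    """Marginal log-likelihood: sum_i log sum_g p(y_i | g, theta) p(g | x_i)."""
    fam = get_family(family)
    if fam.has_scale and theta.sigma2 is None:
        raise ValueError("gaussian family requires sigma2")
    per = logsumexp(_log_post(design) + _log_pdf_matrix(theta, design, fam), axis=1)
    out = float(design.weights @ per)
    if not np.isfinite(out):
        bad = int(np.argmax(~np.isfinite(per)))
        raise FloatingPointError(f"non-finite log-likelihood at row {bad}")
    return out


def responsibilities(theta: Theta, design: Design, family: str | Family) -> np.ndarray:
    """(N, 3) E-step weights: p(G=g | y, x, theta), rows sum to 1."""
    fam = get_family(family)
    logw = _log_post(design) + _log_pdf_matrix(theta, design, fam)
    logw -= logsumexp(logw, axis=1, keepdims=True)
    return np.exp(logw)


def _gradient(theta: Theta, design: Design, fam: Family,
              include_scale: bool) -> np.ndarray:
    """Analytic gradient of the marginal log-likelihood.

    Components ordered (alpha, beta, gamma..., [sigma2]).  Uses the Fisher
    identity: grad = sum_i w_i sum_g resp_ig * score_complete(i, g).
    """
    W = responsibilities(theta, design, fam)
    eta = _eta_matrix(theta, design)
    mu = fam.linkinv(eta)
    r = design.y[:, None] - mu
    if fam.has_scale:
        r_coef = r / theta.sigma2
    else:
        r_coef = r
    fw = design.weights
    a = (W * r_coef).sum(axis=1) * fw          # per-individual score factor
    b = (W * r_coef * _G[None, :]).sum(axis=1) * fw
    grad = [a.sum(), b.sum()]
    if design.n_covariates:
        grad.extend(design.Z.T @ a)
    if include_scale:
        s2 = theta.sigma2
        ds = (W * (-0.5 / s2 + r**2 / (2.0 * s2**2))).sum(axis=1) * fw
        grad.append(ds.sum())
    return np.asarray(grad)


def _theta_from_vector(v: np.ndarray, c: int, include_scale: bool,
                       fixed_sigma2: float | None = None) -> Theta:
    if include_scale:
        return Theta(alpha=v[0], beta=v[1], gamma=v[2 : 2 + c], sigma2=v[2 + c])
    return Theta(alpha=v[0], beta=v[1], gamma=v[2 : 2 + c], sigma2=fixed_sigma2)


def observed_information(
    theta: Theta, design: Design, family: str | Family = "gaussian",
    include_scale: bool | None = None,
) -> np.ndarray:
    """Observed Fisher information of the marginal log-likelihood.

    Central finite differences of the analytic gradient, step
    1e-5 * max(1, |theta_j|).  For the Gaussian family sigma^2 is included as
    the last parameter unless ``include_scale=False``.
    """
    fam = get_family(family)
    if include_scale is None:
        include_scale = fam.has_scale
    c = design.n_covariates
    v0 = theta.coef_vector()
    if include_scale:
        v0 = np.append(v0, theta.sigma2)
    p = v0.size
    J = np.empty((p, p))
    for j in range(p):
        h = 1e-5 * max(1.0, abs(v0[j]))
        if include_scale and j == p - 1:
            # keep sigma2 strictly positive under perturbation
            h = min(h, 0.5 * v0[j])
            if h <= 0:
                raise FloatingPointError("degenerate fit: sigma2 collapsed to 0")
        vp, vm = v0.copy(), v0.copy()
        vp[j] += h
        vm[j] -= h
        gp = _gradient(_theta_from_vector(vp, c, include_scale, theta.sigma2),
                       design, fam, include_scale)
        gm = _gradient(_theta_from_vector(vm, c, include_scale, theta.sigma2),
                       design, fam, include_scale)
        J[:, j] = -(gp - gm) / (2.0 * h)
    return 0.5 * (J + J.T)


def fisher_se(
    theta_hat: Theta, design: Design, family: str | Family = "gaussian"
) -> tuple[float, np.ndarray]:
    """Standard errors from the inverse observed information at the optimum.

    Returns (se_beta, se-vector over (alpha, beta, gamma...)).  A
    non-positive-definite information matrix yields NaN SEs with a warning.
    """
    J = observed_information(theta_hat, design, family)
    ncoef = 2 + design.n_covariates
    try:
        cov = np.linalg.inv(J)
        diag = np.diag(cov)[:ncoef]
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        warnings.warn("observed information not positive definite; SEs unavailable")
        se = np.full(ncoef, np.nan)
    return float(se[1]), se


def _wald_p(beta: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return np.nan
    return float(stats.chi2.sf((beta / se) ** 2, df=1))


def _check_estimable(design: Design) -> None:
    d = design.post.dosage
    w = design.weights
    m = w @ d / w.sum()
    if w @ (d - m) ** 2 / w.sum() < _DOSAGE_VAR_MIN:
        raise NonEstimableSiteError(
            "posterior dosage variance below 1e-8; genotype effect not estimable"
        )


def fit_dosage(design: Design, family: str | Family = "gaussian") -> LatentGlmFit:
    """Standard GLM of y on (1, dosage, covariates) with a Wald test on the dosage."""
    _check_estimable(design)
    fam = get_family(family)
    X = design.dosage_design()
    res = fit_weighted_glm(X, design.y, fam, weights=design.freq_weights)
    se = np.sqrt(np.diag(res["cov"]))
    theta = Theta.from_coef_vector(res["beta"], sigma2=res["scale"])
    return LatentGlmFit(
        theta=theta,
        se_beta=float(se[1]),
        se=se,
        loglik=res["loglik"],
        iterations=res["iterations"],
        converged=res["converged"],
        pvalue=_wald_p(theta.beta, se[1]),
        method="dosage",
    )


def prime_from_dosage(design: Design, family: str | Family = "gaussian") -> Theta:
    """EM starting values: coefficients of the dosage regression."""
    return fit_dosage(design, family).theta


def _m_step(design, fam, resp, X_exp, y_exp, beta0):
    w = (design.weights[:, None] * resp).ravel()
    res = fit_weighted_glm(X_exp, y_exp, fam, weights=w, beta0=beta0, tol=1e-8)
    return res["beta"], res["scale"]


def fit_latent(
    design: Design,
    family: str | Family = "gaussian",
    prime: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> LatentGlmFit:
    """Fit the latent-genotype GLM by EM.

    E-step: responsibilities resp_ig proportional to post_ig * p(y_i | g, theta).
    M-step: weighted GLM on the 3N expanded rows (closed-form WLS for
    Gaussian, with sigma^2 <- sum_ig w_ig (y_i - eta_ig)^2 / N; inner IRLS run
    to convergence for binomial/poisson so the marginal log-likelihood is
    non-decreasing every iteration).  Stops when |delta loglik| < tol.

    Non-convergence is reported via ``converged=False`` (best iterate kept),
    never raised.
    """
    _check_estimable(design)
    fam = get_family(family)
    X_exp, y_exp = design.expanded_design()

    if prime:
        theta = prime_from_dosage(design, fam)
    else:
        gamma0 = np.zeros(design.n_covariates)
        s2 = None
        if fam.has_scale:
            w = design.weights
            ybar = w @ design.y / w.sum()
            s2 = max(float(w @ (design.y - ybar) ** 2 / w.sum()), 1e-12)
        theta = Theta(alpha=0.0, beta=0.0, gamma=gamma0, sigma2=s2)

    ll = loglik(theta, design, fam)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resp = responsibilities(theta, design, fam)
        coef, scale = _m_step(design, fam, resp, X_exp, y_exp, theta.coef_vector())
        theta = Theta.from_coef_vector(coef, sigma2=scale)
        ll_new = loglik(theta, design, fam)
        path.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    se_beta, se = fisher_se(theta, design, fam)
    return LatentGlmFit(
        theta=theta,
        se_beta=se_beta,
        se=se,
        loglik=ll,
        iterations=it,
        converged=converged,
        pvalue=_wald_p(theta.beta, se_beta),
        method="latent",
        loglik_path=np.asarray(path),
    )


def _null_fit(design: Design, fam: Family):
    """GLM of y on (1, Z): the null model with no genotype term."""
    n, c = design.n, design.n_covariates
    X = np.empty((n, 1 + c))
    X[:, 0] = 1.0
    if c:
        X[:, 1:] = design.Z
    res = fit_weighted_glm(X, design.y, fam, weights=design.freq_weights)
    b = res["beta"]
    return Theta(alpha=b[0], beta=0.0, gamma=b[1:], sigma2=res["scale"])


def score_test(design: Design, family: str | Family = "gaussian") -> tuple[float, float]:
    """Score test of beta = 0 in the latent-genotype likelihood.

    The score of the marginal log-likelihood with respect to beta is evaluated
    at beta = 0 with (alpha, gamma) at their null MLE, and standardized by the
    efficient information (the beta block of the observed information with
    the other coefficients profiled out; the Gaussian scale is held at its
    null MLE).  The statistic is asymptotically chi-square(1) under the null.

    Returns (statistic, pvalue).  A site with no posterior dosage variance
    gives (0, 1).
    """
    fam = get_family(family)
    d = design.post.dosage
    w = design.weights
    if w @ (d - w @ d / w.sum()) ** 2 / w.sum() < _DOSAGE_VAR_MIN:
        return 0.0, 1.0
    theta0 = _null_fit(design, fam)
    U = _gradient(theta0, design, fam, include_scale=False)[1]
    J = observed_information(theta0, design, fam, include_scale=False)
    keep = np.arange(J.shape[0]) != 1
    Jnn = J[np.ix_(keep, keep)]
    Jbn = J[1, keep]
    try:
        i_eff = float(J[1, 1] - Jbn @ np.linalg.solve(Jnn, Jbn))
    except np.linalg.LinAlgError:
        raise SingularFitError("null-model information is singular")
    if i_eff <= _DOSAGE_VAR_MIN:
        return 0.0, 1.0
    stat = float(U**2 / i_eff)
    return stat, float(stats.chi2.sf(stat, df=1))


def fit_hybrid(
    design: Design,
    family: str | Family = "gaussian",
    screen_alpha: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> LatentGlmFit:
    """Score-test screen followed by the full EM fit on passing sites.

    Sites with score p >= screen_alpha report the score p-value and no effect
    estimate (``branch='score'``); sites passing the screen are refitted with
    :func:`fit_latent` and report its estimate exactly (``branch='em'``).
    """
    stat, p = score_test(design, family)
    if p < screen_alpha:
        fit = fit_latent(design, family, tol=tol, max_iter=max_iter)
        fit.method = "hybrid"
        fit.branch = "em"
        return fit
    return LatentGlmFit(
        theta=Theta(alpha=np.nan, beta=np.nan, gamma=np.full(design.n_covariates, np.nan)),
        se_beta=np.nan,
        se=None,
        loglik=np.nan,
        iterations=0,
        converged=True,
        pvalue=p,
        statistic=stat,
        method="hybrid",
        branch="score",
    )
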