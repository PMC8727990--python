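"""Weighted generalized linear models (internal).

Minimal IRLS machinery shared by the dosage regression, the EM M-step (which
needs responsibility-weighted expanded designs) and the null fits of the score
test.  Weights are prior/frequency weights: the log-likelihood is the
weighted sum of per-row log-densities.  Gaussian uses the MLE scale
(residual sum of squares divided by the total weight, not by n - p) so that
the certain-genotype reduction of the latent model is exact.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

_MU_EPS = 1e-10


class SingularFitError(ValueError):
    """Design matrix (with intercept) is rank deficient."""


class Family:
    """A GLM family with canonical link."""

    name: str
    has_scale: bool = False

    def linkinv(self, eta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def log_pdf(self, y: np.ndarray, eta: np.ndarray, scale: float | None) -> np.ndarray:
        raise NotImplementedError

    def irls_z_w(self, y, eta):
        """Working response and weight for one IRLS step (canonical link)."""
        raise NotImplementedError


class Gaussian(Family):
    name = "gaussian"
    has_scale = True

    def linkinv(self, eta):
        return eta

    def log_pdf(self, y, eta, scale):
        return -0.5 * (np.log(2.0 * np.pi * scale) + (y - eta) ** 2 / scale)

    def irls_z_w(self, y, eta):
        return y, np.ones_like(eta)


class Binomial(Family):
    name = "binomial"

    def linkinv(self, eta):
        return 1.0 / (1.0 + np.exp(-eta))

    def log_pdf(self, y, eta, scale=None):
        # numerically stable log Bernoulli: y*eta - log(1 + e^eta)
        return y * eta - np.logaddexp(0.0, eta)

    def irls_z_w(self, y, eta):
        mu = np.clip(self.linkinv(eta), _MU_EPS, 1.0 - _MU_EPS)
        w = mu * (1.0 - mu)
        return eta + (y - mu) / w, w


class Poisson(Family):
    name = "poisson"

    def linkinv(self, eta):
        return np.exp(eta)

    def log_pdf(self, y, eta, scale=None):
        from scipy.special import gammaln

        return y * eta - np.exp(eta) - gammaln(y + 1.0)

    def irls_z_w(self, y, eta):
        mu = np.maximum(self.linkinv(eta), _MU_EPS)
        return eta + (y - mu) / mu, mu


FAMILIES = {"gaussian": Gaussian(), "binomial": Binomial(), "poisson": Poisson()}


def get_family(family: "str | Family") -> Family:
    if isinstance(family, Family):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")


def _wls(X, y, w):
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    try:
        c = cho_factor(XtWX)
    except LinAlgError:
        raise SingularFitError("collinear design (X^T W X not positive definite)")
    beta = cho_solve(c, Xw.T @ y)
    return beta, c, XtWX


def fit_weighted_glm(
    X: np.ndarray,
    y: np.ndarray,
    family: "str | Family",
    weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Fit a GLM with prior weights by IRLS (closed form for Gaussian).

    Returns
    -------
    dict with keys: beta, cov (inverse weighted information, scaled by the MLE
    sigma^2 for Gaussian), scale (Gaussian sigma^2 MLE, else None), loglik,
    iterations, converged.
    """
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    wtot = w.sum()

    if fam.has_scale:
        beta, c, _ = _wls(X, y, w)
        resid = y - X @ beta
        scale = float(w @ resid**2 / wtot)
        scale = max(scale, 1e-300)
        cov = cho_solve(c, np.eye(X.shape[1])) * scale
        ll = float(w @ fam.log_pdf(y, X @ beta, scale))
        return dict(beta=beta, cov=cov, scale=scale, loglik=ll,
                    iterations=1, converged=True)

    beta = np.zeros(X.shape[1]) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        z, irls_w = fam.irls_z_w(y, eta)
        beta, c, _ = _wls(X, z, w * irls_w)
        ll = float(w @ fam.log_pdf(y, X @ beta, None))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    _, irls_w = fam.irls_z_w(y, eta)
    _, c, _ = _wls(X, np.zeros_like(y), w * irls_w)
    cov = cho_solve(c, np.eye(X.shape[1]))
    ll = float(w @ fam.log_pdf(y, eta, None))
    return dict(beta=beta, cov=cov, scale=None, loglik=ll,
                iterations=it, converged=converged)
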