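"""Maximum-likelihood allele-frequency estimation from genotype likelihoods.

Two estimators, both EM:

* :func:`estimate_sample_af` — the pooled sample allele frequency f, assuming
  a homogeneous population in Hardy-Weinberg equilibrium.
* :func:`estimate_pop_freqs` — per-population frequencies F given *known*
  admixture proportions Q, where each individual's prior frequency is the
  admixture-weighted average pi_i = sum_k Q_ik F_k.  This is the
  fixed-Q special case of the admixture-model frequency update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .genoprob import GenotypeLikelihoods, GenotypePrior, posterior

__all__ = ["FrequencyEstimate", "estimate_sample_af", "estimate_pop_freqs"]

_CLAMP = 1e-6  # keep frequencies off the boundary during iteration


class UninformativeDataError(ValueError):
    """No likelihood row distinguishes the genotypes."""


@dataclass
class FrequencyEstimate:
    """Result of an EM frequency fit.

    Either ``f`` (sample AF) or ``F`` (per-population frequencies) is set.
    ``loglik`` is the marginal log-likelihood at the estimate, up to the
    additive constant implied by the scaling of the likelihood rows.
    """

    f: float | None = None
    F: np.ndarray | None = None
    loglik: float = np.nan
    iterations: int = 0
    converged: bool = False


def _marginal_loglik(gl: GenotypeLikelihoods, pi: np.ndarray,
                     weights: np.ndarray | None = None) -> float:
    """sum_i w_i log sum_g gl_ig * HWE(pi_i)_g."""
    pi = pi[:, None]
    prior = np.hstack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2])
    with np.errstate(divide="ignore"):
        per = logsumexp(gl.log_gl + np.log(prior), axis=1)
    if weights is None:
        return float(per.sum())
    return float(weights @ per)


def _informative_rows(gl: GenotypeLikelihoods) -> np.ndarray:
    return ~np.all(np.isclose(gl.log_gl, gl.log_gl[:, :1]), axis=1)


def estimate_sample_af(
    gl: GenotypeLikelihoods,
    f0: float = 0.25,
    tol: float = 1e-8,
    max_iter: int = 200,
    weights: np.ndarray | None = None,
) -> FrequencyEstimate:
    """EM estimate of the pooled sample allele frequency.

    Iterates f <- (1/2N) sum_i E[G_i | gl_i, f], where the expectation is the
    posterior dosage under the HWE prior at the current f.  Converges when
    |delta f| < tol.  The marginal likelihood is non-decreasing across
    iterations (standard EM).  ``weights`` are frequency weights for grouped
    rows (row i stands for weights[i] identical individuals).
    """
    if gl.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if not _informative_rows(gl).any():
        raise UninformativeDataError("every likelihood row is constant")
    w = None if weights is None else np.asarray(weights, dtype=float)
    wtot = float(gl.n_individuals) if w is None else float(w.sum())
    f = float(f0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post = posterior(gl, GenotypePrior.sample_af(f))
        d = post.dosage if w is None else w * post.dosage
        f_new = float(d.sum() / (2.0 * wtot))
        f_new = min(max(f_new, 0.0), 1.0)
        if abs(f_new - f) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    return FrequencyEstimate(
        f=f,
        loglik=_marginal_loglik(gl, np.full(gl.n_individuals, f), w),
        iterations=it,
        converged=converged,
    )


def estimate_pop_freqs(
    gl: GenotypeLikelihoods,
    Q: np.ndarray,
    F0: float | np.ndarray = 0.25,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> FrequencyEstimate:
    """EM estimate of per-population allele frequencies with admixture known.

    Maximizes sum_i log sum_g gl_ig p(g | pi_i(F)) over F, with
    pi_i(F) = sum_k Q_ik F_k and an HWE genotype prior given pi_i.  Each of an
    individual's two allele copies originates from population k with
    probability Q_ik; the E-step attributes the expected minor/major allele
    counts to populations and the M-step is the ratio of expected minor-copy
    counts to expected total copies per population.

    Frequencies are clamped to [1e-6, 1 - 1e-6] during iteration so the HWE
    prior never degenerates; if the maximum is at the boundary the reported
    value is unclamped to 0 or 1.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    n, K = Q.shape
    if n != gl.n_individuals:
        raise ValueError("Q rows must match the number of individuals")
    if np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("admixture rows must sum to 1")
    F = np.broadcast_to(np.asarray(F0, dtype=float), (K,)).copy()

    eff_weight = Q.sum(axis=0)  # expected copies contributed per population
    ill = eff_weight < 1e-9
    if ill.any():
        import warnings

        warnings.warn("population(s) with ~zero total admixture weight; "
                      "frequency not identifiable, reporting 0.5")

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pi = np.clip(Q @ F, _CLAMP, 1 - _CLAMP)
        post = posterior(gl, GenotypePrior.individual_af(pi))
        eg = post.dosage  # expected minor-allele copies per individual
        # attribute allele copies to populations: a minor copy came from k
        # w.p. Q_ik F_k / pi_i, a major copy w.p. Q_ik (1-F_k) / (1-pi_i)
        minor_k = (eg / pi)[:, None] * Q * F[None, :]
        major_k = ((2.0 - eg) / (1.0 - pi))[:, None] * Q * (1.0 - F)[None, :]
        denom = minor_k.sum(axis=0) + major_k.sum(axis=0)
        F_new = np.where(denom > 0, minor_k.sum(axis=0) / np.maximum(denom, 1e-300), 0.5)
        F_new = np.clip(F_new, _CLAMP, 1 - _CLAMP)
        F_new[ill] = 0.5
        if np.max(np.abs(F_new - F)) < tol:
            F = F_new
            converged = True
            break
        F = F_new

    # unclamp boundary solutions
    F_report = F.copy()
    F_report[F <= _CLAMP * 1.01] = np.where(
        _boundary_improves(gl, Q, F, np.flatnonzero(F <= _CLAMP * 1.01), 0.0),
        0.0, F[F <= _CLAMP * 1.01])
    F_report[F >= 1 - _CLAMP * 1.01] = np.where(
        _boundary_improves(gl, Q, F, np.flatnonzero(F >= 1 - _CLAMP * 1.01), 1.0),
        1.0, F[F >= 1 - _CLAMP * 1.01])
    if ill.any():
        converged = False
    return FrequencyEstimate(
        F=F_report,
        loglik=_marginal_loglik(gl, np.clip(Q @ F_report, 0.0, 1.0)),
        iterations=it,
        converged=converged,
    )


def _boundary_improves(gl, Q, F, idx, bound) -> np.ndarray:
    """For each index in idx, does snapping F_k to the boundary not lower the likelihood?"""
    if idx.size == 0:
        return np.array([], dtype=bool)
    base = _marginal_loglik(gl, np.clip(Q @ F, 0.0, 1.0))
    out = np.empty(idx.size, dtype=bool)
    for j, k in enumerate(idx):
        Fb = F.copy()
        Fb[k] = bound
        out[j] = _marginal_loglik(gl, np.clip(Q @ Fb, 0.0, 1.0)) >= base - 1e-12
    return out
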