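"""Genotype likelihoods, priors, posteriors, dosages and the imputation info measure.

A biallelic site observed through low-depth sequencing yields, per individual,
a genotype likelihood: p(reads | G = g) for g in {0, 1, 2} copies of the minor
allele.  Combining the likelihood with a Hardy-Weinberg prior built from an
allele frequency (the pooled sample frequency, or an individual-specific
admixture-weighted frequency) gives the genotype posterior, whose expectation
is the genetic dosage used in downstream association models.

Likelihood rows are stored in log space; only ratios within a row matter, so
rows may be rescaled by any positive constant without changing posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GenotypeLikelihoods",
    "GenotypePrior",
    "GenotypePosterior",
    "hwe_prior",
    "individual_allele_frequency",
    "posterior",
    "dosage",
    "info_measure",
    "simulate_genotype_likelihoods",
]

GENOTYPES = np.array([0, 1, 2])


class DegenerateSiteError(ValueError):
    """A likelihood row is identically zero (no genotype can explain the reads)."""


def hwe_prior(freq: float) -> np.ndarray:
    """Genotype distribution ((1-f)^2, 2f(1-f), f^2) under Hardy-Weinberg equilibrium.

    Parameters
    ----------
    freq : float
        Minor-allele frequency in [0, 1].
    """
    f = float(freq)
    if not (0.0 <= f <= 1.0) or not np.isfinite(f):
        raise ValueError(f"allele frequency must be in [0, 1], got {freq}")
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f**2])


def individual_allele_frequency(Q: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Admixture-weighted allele frequencies pi_i = sum_k Q_ik F_k.

    Parameters
    ----------
    Q : (N, K) array
        Admixture proportions; each row must sum to 1 (tolerance 1e-6).
    F : (K,) array
        Minor-allele frequency of the site in each ancestral population.

    Returns
    -------
    (N,) array of per-individual allele frequencies, each in [min F, max F].
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if Q.shape[1] != F.shape[0]:
        raise ValueError(f"Q has {Q.shape[1]} populations but F has {F.shape[0]}")
    if np.any((F < 0) | (F > 1)):
        raise ValueError("population frequencies must lie in [0, 1]")
    rowsums = Q.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(rowsums - 1.0)))
        raise ValueError(
            f"admixture rows must sum to 1; row {bad} sums to {rowsums[bad]:.8f}"
        )
    return Q @ F


@dataclass
class GenotypeLikelihoods:
    """Per-individual genotype likelihoods at one biallelic site, in log space.

    Attributes
    ----------
    log_gl : (N, 3) array
        log p(reads | G = g); rows are defined up to an additive constant.
    depth : (N,) int array
        Read count per individual.  Depth-0 rows carry no information and are
        constant across genotypes.
    site_id : str
        Marker label.
    """

    log_gl: np.ndarray
    depth: np.ndarray
    site_id: str = "site"

    def __post_init__(self) -> None:
        self.log_gl = np.atleast_2d(np.asarray(self.log_gl, dtype=float))
        self.depth = np.atleast_1d(np.asarray(self.depth))
        if self.log_gl.shape != (self.depth.shape[0], 3):
            raise ValueError("log_gl must be N x 3 with matching depth vector")
        if np.any(np.isnan(self.log_gl)) or np.any(self.log_gl == np.inf):
            raise ValueError("log-likelihoods must be finite or -inf")

    @classmethod
    def from_linear(
        cls, values: np.ndarray, depth: np.ndarray | None = None, site_id: str = "site"
    ) -> "GenotypeLikelihoods":
        """Build from linear-scale likelihoods (rows may be arbitrarily scaled)."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("likelihoods must be finite and non-negative")
        if np.any(values.sum(axis=1) == 0):
            bad = int(np.argmax(values.sum(axis=1) == 0))
            raise DegenerateSiteError(f"all-zero likelihood row for individual {bad}")
        if depth is None:
            # unknown depth: flag informationless (constant) rows as depth 0
            const = np.all(values == values[:, :1], axis=1)
            depth = np.where(const, 0, 1)
        with np.errstate(divide="ignore"):
            log_gl = np.log(values)
        return cls(log_gl=log_gl, depth=np.asarray(depth, dtype=int), site_id=site_id)

    @property
    def n_individuals(self) -> int:
        return self.log_gl.shape[0]


@dataclass
class GenotypePrior:
    """Frequency prior for the genotype: pooled sample AF or individual AF.

    kind == "sample_af": a single frequency ``f`` shared by all individuals.
    kind == "individual_af": a per-individual vector ``pi`` of admixture-weighted
    frequencies (use :func:`individual_allele_frequency` to build it).
    """

    kind: str
    f: float | None = None
    pi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "sample_af":
            if self.f is None or self.pi is not None:
                raise ValueError("sample_af prior takes f only")
            if not (0.0 <= self.f <= 1.0):
                raise ValueError("f must be in [0, 1]")
        elif self.kind == "individual_af":
            if self.pi is None or self.f is not None:
                raise ValueError("individual_af prior takes pi only")
            self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
            if np.any((self.pi < 0) | (self.pi > 1)):
                raise ValueError("pi must lie in [0, 1]")
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")

    @classmethod
    def sample_af(cls, f: float) -> "GenotypePrior":
        return cls(kind="sample_af", f=f)

    @classmethod
    def individual_af(cls, pi: np.ndarray) -> "GenotypePrior":
        return cls(kind="individual_af", pi=pi)

    def frequencies(self, n: int) -> np.ndarray:
        """Per-individual prior frequency vector of length n."""
        if self.kind == "sample_af":
            return np.full(n, float(self.f))
        if self.pi.shape[0] != n:
            raise ValueError(f"prior has {self.pi.shape[0]} individuals, data has {n}")
        return self.pi


@dataclass
class GenotypePosterior:
    """Genotype posterior probabilities and dosages for one site."""

    probs: np.ndarray
    dosage: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.probs.shape[1] != 3:
            raise ValueError("posterior must be N x 3")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError("posterior rows must sum to 1")
        self.dosage = self.probs[:, 1] + 2.0 * self.probs[:, 2]

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]


def posterior(gl: GenotypeLikelihoods, prior: GenotypePrior) -> GenotypePosterior:
    """Genotype posterior p(G | reads) by Bayes' rule with an HWE frequency prior.

    Each row is gl_ig * hwe_prior(freq_i)_g, normalized.  Individuals with no
    reads get exactly their prior back.  Normalization is done in log space
    (max subtraction) so deep-coverage rows do not underflow.
    """
    fr = prior.frequencies(gl.n_individuals)[:, None]
    prior_probs = np.hstack([(1 - fr) ** 2, 2 * fr * (1 - fr), fr**2])
    with np.errstate(divide="ignore"):
        log_prior = np.log(prior_probs)
    log_post = gl.log_gl + log_prior
    norm = logsumexp(log_post, axis=1, keepdims=True)
    if np.any(~np.isfinite(norm)):
        bad = int(np.argmax(~np.isfinite(norm.ravel())))
        raise DegenerateSiteError(
            f"posterior undefined for individual {bad}: prior excludes every "
            "genotype the reads allow"
        )
    probs = np.exp(log_post - norm)
    return GenotypePosterior(probs=probs)


def dosage(post: GenotypePosterior) -> np.ndarray:
    """Expected genotype E[G] = p(G=1) + 2 p(G=2) per individual."""
    return post.probs[:, 1] + 2.0 * post.probs[:, 2]


def info_measure(dosages: np.ndarray, freq: float) -> float:
    """MACH-style imputation info: Var(dosage) / (2 f (1 - f)).

    The ratio of the observed dosage variance to the binomial variance of the
    true genotype under Hardy-Weinberg equilibrium; approaches 1 when
    genotypes are known with certainty.  The empirical variance uses the N-1
    denominator.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 individuals")
    if not (0.0 < freq < 1.0):
        raise ValueError("info measure undefined for monomorphic frequency")
    return float(np.var(d, ddof=1) / (2.0 * freq * (1.0 - freq)))


def read_log_likelihood(depth: np.ndarray, n_minor: np.ndarray,
                        error_rate: float) -> np.ndarray:
    """Log genotype likelihoods from (read count, minor-allele read count) pairs.

    Each read reports the minor allele with probability g/2*(1-e) + (1-g/2)*e
    for genotype g, independently across reads, so the likelihood is binomial
    in the minor-read count (the binomial coefficient, constant across g, is
    dropped).
    """
    depth = np.atleast_1d(np.asarray(depth, dtype=float))
    k = np.atleast_1d(np.asarray(n_minor, dtype=float))
    e = float(error_rate)
    p_minor = np.array([e, 0.5, 1.0 - e])  # per-read P(minor | g)
    return (k[:, None] * np.log(p_minor)[None, :]
            + (depth - k)[:, None] * np.log1p(-p_minor)[None, :])


def simulate_genotype_likelihoods(
    genotypes: np.ndarray,
    mean_depth: float | np.ndarray,
    error_rate: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> GenotypeLikelihoods:
    """Simulate sequencing-read genotype likelihoods for known genotypes.

    Per individual, the read count is Poisson(mean_depth) and each read
    reports the minor allele with probability g/2*(1-e) + (1-g/2)*e.

    Parameters
    ----------
    genotypes : (N,) int array in {0, 1, 2}
    mean_depth : scalar or (N,) array of positive means
    error_rate : per-read error probability, in (0, 0.5)
    rng : numpy Generator or seed
    """
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    rng = np.random.default_rng(rng)
    g = np.atleast_1d(np.asarray(genotypes, dtype=int))
    mean_depth = np.broadcast_to(np.asarray(mean_depth, dtype=float), g.shape)
    depth = rng.poisson(mean_depth)
    p_minor_true = g / 2.0 * (1.0 - error_rate) + (1.0 - g / 2.0) * error_rate
    n_minor = rng.binomial(depth, p_minor_true)
    log_gl = read_log_likelihood(depth, n_minor, error_rate)
    return GenotypeLikelihoods(log_gl=log_gl, depth=depth)
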