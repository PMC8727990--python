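import numpy as np
import pytest

from latentgwas import (
    Design,
    GenotypePosterior,
    GenotypePrior,
    posterior,
    simulate_genotype_likelihoods,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def degenerate_posterior(genotypes):
    """Posterior with all mass on the true genotype (certain data)."""
    return GenotypePosterior(probs=np.eye(3)[np.asarray(genotypes, dtype=int)])


def simulated_design(rng, n=200, f=0.3, beta=0.4, depth=2.0, family="gaussian",
                     prior_f=None, n_cov=0, gamma=None):
    """A small single-site cohort: genotypes, reads, posterior, phenotype."""
    g = rng.binomial(2, f, n)
    Z = rng.normal(size=(n, n_cov)) if n_cov else None
    eta = beta * g + (Z @ gamma if n_cov else 0.0)
    if family == "gaussian":
        y = eta + rng.normal(size=n)
    elif family == "binomial":
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    else:
        y = rng.poisson(np.exp(0.1 * eta)).astype(float)
    gl = simulate_genotype_likelihoods(g, depth, 0.01, rng)
    post = posterior(gl, GenotypePrior.sample_af(f if prior_f is None else prior_f))
    return Design(y=y, post=post, Z=Z), g


@pytest.fixture
def make_design(rng):
    def _make(**kw):
        return simulated_design(rng, **kw)

    return _make
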