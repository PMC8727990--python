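"""Synthetic cohorts for power, false-positive-rate and bias experiments.

Two study designs are generated:

* quantitative-trait cohorts (:func:`simulate_cohort`): N individuals with a
  normally distributed phenotype (SD 1) whose mean is beta*g (+ gamma*q under
  population structure, where q is the admixture proportion of population 1),
  sequenced at a low/high two-level depth that may be correlated with the
  phenotype through the parameter delta;
* large case-control studies (:func:`simulate_case_control`): a disease with
  given prevalence and multiplicative per-allele relative risk, cases and
  controls sequenced at different mean depths, optionally discarding
  individuals with zero reads.

:func:`run_power_experiment` replicates either design, runs the requested
association methods on every replicate and tabulates power / false-positive
rate, effect-size bias, mean standard errors and per-stratum imputation info.
All randomness flows from a single master seed via ``numpy`` seed sequences,
so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import genoprob
from .freqs import estimate_pop_freqs, estimate_sample_af
from .genoprob import (
    GenotypeLikelihoods,
    GenotypePrior,
    hwe_prior,
    individual_allele_frequency,
    posterior,
    read_log_likelihood,
)
from .glm import fit_weighted_glm
from .latent_glm import (
    Design,
    LatentGlmFit,
    NonEstimableSiteError,
    Theta,
    fit_dosage,
    fit_hybrid,
    fit_latent,
    score_test,
)

__all__ = [
    "ScenarioConfig",
    "CaseControlConfig",
    "SimulatedCohort",
    "SCENARIOS",
    "scenario_config",
    "case_control_config",
    "assign_depth",
    "simulate_cohort",
    "simulate_case_control",
    "case_genotype_distributions",
    "run_power_experiment",
]

METHODS = ("truth", "dosage", "latent", "score", "hybrid")


@dataclass
class ScenarioConfig:
    """Recipe for a quantitative-trait cohort.

    ``delta`` in [0, 1] controls depth-phenotype correlation: individuals in
    the top half of the phenotype distribution land in the high-depth group
    with probability 0.5 + delta/2 (0.5 - delta/2 otherwise), so delta=0 is
    independent assignment and delta=1 a deterministic split.
    """

    n_individuals: int = 1000
    allele_freq: float | tuple[float, float] = 0.45
    structured: bool = False
    beta: float = 0.0
    gamma: float = 0.0
    delta: float = 0.0
    depth_levels: tuple[float, float] = (1.0, 4.0)
    error_rate: float = 0.01
    family: str = "gaussian"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.structured:
            if np.ndim(self.allele_freq) != 1 or len(self.allele_freq) != 2:
                raise ValueError("structured scenarios need 2 population frequencies")
        elif np.ndim(self.allele_freq) != 0:
            raise ValueError("unstructured scenarios take a scalar allele frequency")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must be in [0, 1]")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError("family must be gaussian or binomial")


@dataclass
class CaseControlConfig:
    """Recipe for a case-control cohort with depth differing by status.

    The disease model is multiplicative per allele: p(case | g) = k * rr**g
    with the baseline k solved so the population prevalence matches.
    """

    n_cases: int = 50_000
    n_controls: int = 50_000
    causal_freq: float = 0.05
    prevalence: float = 0.10
    rr: float = 1.0
    depth_cases: float = 4.0
    depth_controls: float = 1.0
    drop_zero_depth: bool = True
    error_rate: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        self.baseline_risk()  # validates solvability

    def baseline_risk(self) -> float:
        """k such that sum_g HWE(f)_g * k * rr**g equals the prevalence."""
        pg = hwe_prior(self.causal_freq)
        k = self.prevalence / float(pg @ np.power(self.rr, [0, 1, 2]))
        if k * self.rr**2 >= 1.0:
            raise ValueError("per-genotype risk exceeds 1; config infeasible")
        return k


@dataclass
class SimulatedCohort:
    """One simulated site with genotypes, phenotype, reads and the truth."""

    genotypes: np.ndarray
    phenotype: np.ndarray
    gl: GenotypeLikelihoods
    depth: np.ndarray
    Q: np.ndarray | None
    truth: "ScenarioConfig | CaseControlConfig"

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


def assign_depth(
    phenotype_or_status: np.ndarray,
    delta: float,
    depth_levels: tuple[float, float],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Assign each individual a low or high mean depth, tied to the phenotype.

    P(high depth) is 0.5 + delta/2 for individuals in the top half of the
    phenotype ranks (or cases), 0.5 - delta/2 otherwise.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must be in [0, 1]")
    rng = np.random.default_rng(rng)
    v = np.asarray(phenotype_or_status, dtype=float)
    n = v.shape[0]
    if set(np.unique(v)) <= {0.0, 1.0}:
        top = v == 1.0
    else:
        top = np.argsort(np.argsort(v, kind="stable"), kind="stable") >= n // 2
    p_high = np.where(top, 0.5 + delta / 2.0, 0.5 - delta / 2.0)
    high = rng.random(n) < p_high
    low_mean, high_mean = depth_levels
    return np.where(high, high_mean, low_mean)


def simulate_cohort(cfg: ScenarioConfig,
                    rng: np.random.Generator | int | None = None) -> SimulatedCohort:
    """Draw one quantitative-trait cohort under the scenario recipe."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n = cfg.n_individuals
    if cfg.structured:
        q1 = rng.uniform(0.0, 1.0, size=n)
        Q = np.column_stack([q1, 1.0 - q1])
        pi = individual_allele_frequency(Q, np.asarray(cfg.allele_freq, dtype=float))
    else:
        Q = None
        pi = np.full(n, float(cfg.allele_freq))
    g = rng.binomial(2, pi)
    mean = cfg.beta * g + (cfg.gamma * Q[:, 0] if cfg.structured else 0.0)
    if cfg.family == "gaussian":
        y = rng.normal(mean, 1.0)
    else:
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-mean))).astype(float)
    depth_mean = assign_depth(y, cfg.delta, cfg.depth_levels, rng)
    gl = genoprob.simulate_genotype_likelihoods(g, depth_mean, cfg.error_rate, rng)
    return SimulatedCohort(genotypes=g, phenotype=y, gl=gl, depth=gl.depth,
                           Q=Q, truth=cfg)


def case_genotype_distributions(cfg: CaseControlConfig) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form genotype distributions p(g | case) and p(g | control)."""
    pg = hwe_prior(cfg.causal_freq)
    k = cfg.baseline_risk()
    risk = k * np.power(cfg.rr, [0, 1, 2])
    p_case = pg * risk / (pg @ risk)
    p_ctrl = pg * (1.0 - risk) / (pg @ (1.0 - risk))
    return p_case, p_ctrl


def simulate_case_control(cfg: CaseControlConfig,
                          rng: np.random.Generator | int | None = None) -> SimulatedCohort:
    """Draw one case-control cohort; phenotype is 0/1 case status."""
    y, g, depth, n_minor = _case_control_arrays(cfg, np.random.default_rng(
        cfg.seed if rng is None else rng))
    gl = GenotypeLikelihoods(
        log_gl=read_log_likelihood(depth, n_minor, cfg.error_rate),
        depth=depth,
    )
    return SimulatedCohort(genotypes=g, phenotype=y.astype(float), gl=gl,
                           depth=depth, Q=None, truth=cfg)


def _case_control_arrays(cfg: CaseControlConfig, rng: np.random.Generator):
    """(status, genotype, depth, minor-read count), zero-depth rows dropped if asked."""
    p_case, p_ctrl = case_genotype_distributions(cfg)
    g = np.concatenate([
        rng.choice(3, size=cfg.n_cases, p=p_case),
        rng.choice(3, size=cfg.n_controls, p=p_ctrl),
    ])
    y = np.concatenate([np.ones(cfg.n_cases, dtype=int),
                        np.zeros(cfg.n_controls, dtype=int)])
    mean_depth = np.where(y == 1, cfg.depth_cases, cfg.depth_controls)
    depth = rng.poisson(mean_depth)
    e = cfg.error_rate
    p_minor = g / 2.0 * (1.0 - e) + (1.0 - g / 2.0) * e
    n_minor = rng.binomial(depth, p_minor)
    if cfg.drop_zero_depth:
        keep = depth > 0
        y, g, depth, n_minor = y[keep], g[keep], depth[keep], n_minor[keep]
    return y, g, depth, n_minor


# ---------------------------------------------------------------------------
# grouped fitting helpers: a case-control site collapses into unique
# (status, depth, minor-read-count) patterns, which makes 100k-individual
# replicates cheap to fit via frequency weights
# ---------------------------------------------------------------------------

def grouped_read_patterns(
    y: np.ndarray, depth: np.ndarray, n_minor: np.ndarray, error_rate: float,
) -> tuple[np.ndarray, GenotypeLikelihoods, np.ndarray]:
    """Collapse individuals into unique (status, depth, minor-reads) patterns.

    Returns (pattern status, pattern GenotypeLikelihoods, pattern counts).
    """
    # integer-encode the (status, depth, minor reads) pattern; bincount is
    # O(N) where a lexicographic unique would sort 100k rows
    dmax = int(depth.max()) + 1
    code = (np.asarray(y, dtype=np.int64) * dmax + depth) * dmax + n_minor
    counts_all = np.bincount(code)
    codes = np.flatnonzero(counts_all)
    counts = counts_all[codes].astype(float)
    pk = codes % dmax
    pd_ = (codes // dmax) % dmax
    py = (codes // (dmax * dmax)).astype(float)
    gl = GenotypeLikelihoods(log_gl=read_log_likelihood(pd_, pk, error_rate),
                             depth=pd_)
    return py, gl, counts


def grouped_case_control_design(
    y: np.ndarray, depth: np.ndarray, n_minor: np.ndarray,
    prior_f: float, error_rate: float,
) -> Design:
    """Collapse individuals into read-pattern groups and build a weighted Design."""
    py, gl, counts = grouped_read_patterns(y, depth, n_minor, error_rate)
    post = posterior(gl, GenotypePrior.sample_af(prior_f))
    return Design(y=py, post=post, freq_weights=counts)


def asymptotic_truth_slope(cfg: CaseControlConfig) -> float:
    """Large-sample limit of the true-genotype logistic slope under the design.

    Case-control sampling identifies the log odds ratio, not log(RR); this is
    the value the true-genotype logistic regression converges to, computed by
    fitting the logistic model to the six (status, genotype) cells with their
    exact probabilities.  Used as the baseline for effect-size bias.
    """
    p_case, p_ctrl = case_genotype_distributions(cfg)
    n_tot = cfg.n_cases + cfg.n_controls
    w = np.concatenate([p_ctrl * cfg.n_controls, p_case * cfg.n_cases]) / n_tot
    cell_y = np.repeat([0.0, 1.0], 3)
    cell_g = np.tile([0.0, 1.0, 2.0], 2)
    X = np.column_stack([np.ones(6), cell_g])
    res = fit_weighted_glm(X, cell_y, "binomial", weights=w)
    return float(res["beta"][1])


def _grouped_truth_fit(y: np.ndarray, g: np.ndarray) -> LatentGlmFit:
    """Logistic GLM of status on the true genotype, fitted on the 6 (y, g) cells."""
    key = y * 3 + g
    counts = np.bincount(key, minlength=6).astype(float)
    cell_y = np.repeat([0.0, 1.0], 3)
    cell_g = np.tile([0.0, 1.0, 2.0], 2)
    keep = counts > 0
    X = np.column_stack([np.ones(keep.sum()), cell_g[keep]])
    res = fit_weighted_glm(X, cell_y[keep], "binomial", weights=counts[keep])
    se = np.sqrt(np.diag(res["cov"]))
    from scipy.stats import chi2

    beta = res["beta"][1]
    return LatentGlmFit(
        theta=Theta(alpha=res["beta"][0], beta=beta),
        se_beta=float(se[1]), se=se, loglik=res["loglik"],
        iterations=res["iterations"], converged=res["converged"],
        pvalue=float(chi2.sf((beta / se[1]) ** 2, 1)), method="truth",
    )


def _weighted_info(dosage: np.ndarray, weights: np.ndarray, freq: float) -> float:
    wtot = weights.sum()
    if wtot < 2:
        return np.nan
    m = weights @ dosage / wtot
    var = weights @ (dosage - m) ** 2 / (wtot - 1.0)
    return float(var / (2.0 * freq * (1.0 - freq)))


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Named quantitative-trait presets scenario1..scenario6.

    The six combinations of genotype effect, population structure and
    depth-phenotype correlation; "correlated" presets default to delta=0.5
    (the correlation strength is swept in experiments).
    """
    base = dict(n_individuals=1000, depth_levels=(1.0, 4.0), error_rate=0.01)
    presets = {
        "scenario1": dict(allele_freq=0.45, beta=0.0, delta=0.5),
        "scenario2": dict(allele_freq=0.45, beta=0.3, delta=0.0),
        "scenario3": dict(allele_freq=(0.9, 0.1), structured=True, beta=0.0,
                          gamma=1.0, delta=0.5),
        "scenario4": dict(allele_freq=(0.9, 0.1), structured=True, beta=0.3,
                          gamma=1.0, delta=0.0),
        "scenario5": dict(allele_freq=0.45, beta=0.3, delta=0.5),
        "scenario6": dict(allele_freq=(0.9, 0.1), structured=True, beta=0.3,
                          gamma=1.0, delta=0.5),
    }
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    return ScenarioConfig(**{**base, **presets[name], **overrides})


def case_control_config(name: str, **overrides) -> CaseControlConfig:
    """Named case-control presets: 'table2' (zero-read individuals removed)
    and 'table3' (kept)."""
    presets = {
        "table2": dict(drop_zero_depth=True),
        "table3": dict(drop_zero_depth=False),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return CaseControlConfig(**{**presets[name], **overrides})


SCENARIOS = tuple(f"scenario{i}" for i in range(1, 7)) + ("table2", "table3")


# ---------------------------------------------------------------------------
# replicated experiments
# ---------------------------------------------------------------------------

def _build_prior(cohort: SimulatedCohort, prior: str):
    """Posterior + frequency actually used, under the requested prior policy."""
    cfg = cohort.truth
    if isinstance(cfg, CaseControlConfig):
        if prior in ("sample_true", "true"):
            f = cfg.causal_freq
        elif prior == "sample_estimated":
            f = estimate_sample_af(cohort.gl).f
        else:
            raise ValueError(f"prior {prior!r} unavailable for case-control designs")
        return posterior(cohort.gl, GenotypePrior.sample_af(f)), f
    if prior in ("sample_true", "true") and not cfg.structured:
        f = float(cfg.allele_freq)
        return posterior(cohort.gl, GenotypePrior.sample_af(f)), f
    if prior == "sample_true" and cfg.structured:
        f = float(np.mean(cfg.allele_freq))  # population-average frequency
        return posterior(cohort.gl, GenotypePrior.sample_af(f)), f
    if prior == "sample_estimated":
        f = estimate_sample_af(cohort.gl).f
        return posterior(cohort.gl, GenotypePrior.sample_af(f)), f
    # unstructured cohorts: the individual prior collapses to K=1 (== sample AF)
    Q = cohort.Q if cfg.structured else np.ones((cohort.n, 1))
    F_true = np.atleast_1d(np.asarray(cfg.allele_freq, dtype=float))
    if prior in ("individual_true", "true"):
        pi = individual_allele_frequency(Q, F_true)
        return posterior(cohort.gl, GenotypePrior.individual_af(pi)), float(pi.mean())
    if prior == "individual_estimated":
        F = estimate_pop_freqs(cohort.gl, Q).F
        pi = individual_allele_frequency(Q, F)
        return posterior(cohort.gl, GenotypePrior.individual_af(pi)), float(pi.mean())
    raise ValueError(f"unknown prior policy {prior!r}")


def _fit_method(method: str, design: Design, family: str,
                truth_y=None, truth_g=None, screen_alpha: float = 0.05):
    if method == "truth":
        if design.freq_weights is not None:
            # grouped case-control path: logistic fit on the (status, g) cells
            return _grouped_truth_fit(np.asarray(truth_y, dtype=int),
                                      np.asarray(truth_g, dtype=int))
        post = genoprob.GenotypePosterior(probs=np.eye(3)[np.asarray(truth_g)])
        d = Design(y=design.y, post=post, Z=design.Z)
        return fit_dosage(d, family)
    if method == "dosage":
        return fit_dosage(design, family)
    if method == "latent":
        return fit_latent(design, family)
    if method == "score":
        stat, p = score_test(design, family)
        return LatentGlmFit(theta=Theta(alpha=np.nan, beta=np.nan),
                            se_beta=np.nan, loglik=np.nan, iterations=0,
                            converged=True, pvalue=p, statistic=stat,
                            method="score")
    if method == "hybrid":
        return fit_hybrid(design, family, screen_alpha=screen_alpha)
    raise ValueError(f"unknown method {method!r}")


def run_power_experiment(
    cfg: "ScenarioConfig | CaseControlConfig",
    n_replicates: int,
    methods: Sequence[str] = ("truth", "dosage", "latent"),
    alpha: float = 1e-5,
    prior: str = "sample_estimated",
    seed: int | None = 0,
    screen_alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate a design, test every replicate with each method, tabulate power.

    Power (or, with a null effect, the false-positive rate) is the fraction of
    replicates with p <= alpha.  For estimating methods the table also reports
    the mean effect estimate, its bias against the generating effect (log RR
    for case-control designs), the mean standard error and, for case-control
    designs, the mean imputation info per case/control stratum.  Replicates
    where a fit fails (non-estimable site, singular design) are counted in
    ``n_failed`` and excluded from the power denominator.

    Per-replicate seeds are spawned from the master ``seed``; results are
    bit-reproducible.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    is_cc = isinstance(cfg, CaseControlConfig)
    family = "binomial" if is_cc else cfg.family
    # bias baseline: case-control sampling identifies the log odds ratio, so
    # compare estimates to the asymptotic true-genotype slope, not log(RR)
    true_beta = asymptotic_truth_slope(cfg) if is_cc else cfg.beta
    rows = {m: dict(p=[], beta=[], se=[], conv=0, fail=0, r2_case=[], r2_ctrl=[])
            for m in methods}
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    for ss in streams:
        rng = np.random.default_rng(ss)
        if is_cc:
            y, g, depth, n_minor = _case_control_arrays(cfg, rng)
            py, gl, counts = grouped_read_patterns(y, depth, n_minor, cfg.error_rate)
            if prior in ("sample_true", "true"):
                prior_f = cfg.causal_freq
            elif prior == "sample_estimated":
                prior_f = estimate_sample_af(gl, weights=counts).f
            else:
                raise ValueError(f"prior {prior!r} unavailable for case-control designs")
            design = Design(y=py, post=posterior(gl, GenotypePrior.sample_af(prior_f)),
                            freq_weights=counts)
            truth_y, truth_g = y, g
            case_mask = design.y == 1.0
        else:
            cohort = simulate_cohort(cfg, rng)
            post, prior_f = _build_prior(cohort, prior)
            Z = cohort.Q[:, :1] if cfg.structured else None
            design = Design(y=cohort.phenotype, post=post, Z=Z)
            truth_y, truth_g = cohort.phenotype, cohort.genotypes
            case_mask = None
        for m in methods:
            acc = rows[m]
            try:
                fit = _fit_method(m, design, family, truth_y, truth_g, screen_alpha)
            except (NonEstimableSiteError, ValueError):
                acc["fail"] += 1
                continue
            acc["p"].append(fit.pvalue)
            acc["conv"] += int(fit.converged)
            if np.isfinite(fit.theta.beta):
                acc["beta"].append(fit.theta.beta)
                acc["se"].append(fit.se_beta)
            if is_cc and m in ("dosage", "latent"):
                w = design.freq_weights
                acc["r2_case"].append(_weighted_info(
                    design.post.dosage[case_mask], w[case_mask], prior_f))
                acc["r2_ctrl"].append(_weighted_info(
                    design.post.dosage[~case_mask], w[~case_mask], prior_f))
    out = []
    for m in methods:
        acc = rows[m]
        pvals = np.asarray(acc["p"], dtype=float)
        n_ok = pvals.size
        betas = np.asarray(acc["beta"], dtype=float)
        out.append({
            "method": m,
            "effect": true_beta,
            "log_rr": float(np.log(cfg.rr)) if is_cc else np.nan,
            "alpha": alpha,
            "n_replicates": n_replicates,
            "n_tested": n_ok,
            "n_failed": acc["fail"],
            "n_converged": acc["conv"],
            "power": float(np.mean(pvals <= alpha)) if n_ok else np.nan,
            "mean_beta": float(betas.mean()) if betas.size else np.nan,
            "bias": float(betas.mean() - true_beta) if betas.size else np.nan,
            "sd_beta": float(betas.std(ddof=1)) if betas.size > 1 else np.nan,
            "mean_se": float(np.mean(acc["se"])) if acc["se"] else np.nan,
            "r2_cases": float(np.mean(acc["r2_case"])) if acc["r2_case"] else np.nan,
            "r2_controls": float(np.mean(acc["r2_ctrl"])) if acc["r2_ctrl"] else np.nan,
        })
    return pd.DataFrame(out)
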