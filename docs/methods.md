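# Methods

## Genotype likelihoods, priors and posteriors

A biallelic site sequenced at depth d in one individual yields reads of
which k report the minor allele.  Each read is assumed to sample one of the
two allele copies uniformly and to report it correctly with probability
1 − ε, so the per-read minor-allele probability under genotype g is
g/2·(1 − ε) + (1 − g/2)·ε and the genotype likelihood is binomial in k
(the binomial coefficient, constant in g, is dropped).  Likelihood rows are
stored in log space and are defined only up to a row-wise constant; all
downstream quantities are invariant to rescaling.

The posterior is p(G = g | x) ∝ p(x | G = g) · p(G = g), with the prior the
Hardy–Weinberg distribution ((1−π)², 2π(1−π), π²) at a frequency π that is
either the pooled sample allele frequency f or the individual allele
frequency π_i = Σ_k q_ik F_k.  Posterior normalization subtracts the row
maximum before exponentiating, so deep-coverage rows do not underflow.
An individual with zero reads gets exactly the prior back.  The dosage is
E[G | x]; the imputation info measure is Var(dosage)/(2f(1−f)) with the
N−1 variance denominator (a fixed convention so tests are bit-stable).

## Frequency estimation

`estimate_sample_af` is the standard EM: f ← (1/2N) Σ_i E[G_i | x_i, f],
initialized at f₀ = 0.25, stopping at |Δf| < 1e-8 or 200 iterations.  The
marginal likelihood is non-decreasing (verified in tests against a dense
grid search).

`estimate_pop_freqs` maximizes the same marginal likelihood over
per-population frequencies F with admixture proportions Q *fixed and known*
(estimating Q is out of scope).  The E-step attributes each expected
minor/major allele copy to a population — a minor copy of individual i came
from population k with probability q_ik F_k / π_i — and the M-step is the
ratio of expected minor copies to expected total copies per population.
Frequencies are clamped to [1e-6, 1−1e-6] during iteration so the prior
never degenerates; a boundary solution is reported as 0 or 1 only if
snapping it there does not lower the likelihood.  A population with
essentially zero total admixture weight is not identifiable: its frequency
is reported as 0.5 with `converged=False` and a warning.

## The latent-genotype GLM

The marginal log-likelihood l(θ) = Σ_i log Σ_g p(y_i | g, z_i, θ) p(g | x_i)
is maximized by EM with the genotype as the latent variable:

* E-step: responsibilities w_ig ∝ p(g | x_i) · p(y_i | g, z_i, θ).
* M-step: a weighted GLM on the 3N-row genotype-expanded design (intercept,
  genotype column g, covariates).  Gaussian: closed-form weighted least
  squares with σ² ← Σ w_ig (y_i − η_ig)² / N.  Binomial/Poisson: inner IRLS
  run to |Δ| < 1e-8, i.e. a full M-step rather than one generalized-EM
  update, which guarantees the marginal log-likelihood is non-decreasing at
  every EM iteration (asserted throughout the test suite via the recorded
  `loglik_path`).

Convergence: |Δ loglik| < 1e-6 (default) or 100 iterations; non-convergence
is reported on the fit object, not raised.  EM is initialized from the
dosage-regression coefficients ("priming"); tests verify priming never moves
the converged optimum and reduces the iteration count in ≥90% of sites.

Covariates are always fitted jointly inside the EM, never residualized out
beforehand: residualizing biases the genotype effect whenever a covariate
correlates with both phenotype and genotype (e.g. conditional analyses on a
linked variant).

**Standard errors** are square roots of the diagonal of the inverse observed
Fisher information of the *marginal* likelihood at the optimum, computed by
central finite differences of the analytic (Fisher-identity) gradient with
step 1e-5·max(1, |θ_j|).  For the Gaussian family σ² is included as a
parameter of the information matrix (its cross-terms with the coefficients
vanish at the MLE, so with certain genotypes the coefficient block reduces
exactly to the OLS covariance σ̂²(XᵀX)⁻¹ with the MLE σ̂²).  The dosage GLM
also uses the MLE scale so that, with certain genotypes, latent and dosage
fits coincide in coefficients, SEs and p-values.  P-values are Wald
(β̂/se)² against χ²₁; a non-positive-definite information matrix yields NaN
SEs with a warning rather than an exception.

**Score test**: the score of the marginal likelihood in β at β = 0 with
(α, γ) at their null MLE, standardized by the efficient information — the
β entry of the observed information with the other *coefficients* profiled
out.  The Gaussian σ² is held at its null MLE (not profiled in the
information), which makes the certain-genotype case agree exactly with the
classical score test for adding the genotype column.  A site whose posterior
dosages have variance below 1e-8 is not testable: the score test returns
(0, 1) and the estimating fits raise a flagged error instead of reporting a
spurious huge SE.

**Hybrid**: run the score test; sites with p below the screen threshold
(default 0.05, configurable) are refitted by EM and report that fit
verbatim; other sites report the score p-value with no effect estimate.
The branch taken is recorded.

**Grouped observations.**  All fits accept frequency weights.  A case-control
site collapses into unique (status, depth, minor-read-count) patterns — a
few hundred patterns for 100,000 individuals — and fitting the weighted
pattern design is algebraically identical to the per-individual fit (tested
to 1e-8).  This is what makes the large simulation studies cheap.

## Simulation engine

### Quantitative-trait scenarios

N = 1,000 individuals (default).  Without structure, genotypes are
Binomial(2, f) at f = 0.45.  With structure, each individual's admixture
proportion q₁ is Uniform(0, 1) across two populations with frequencies
(0.9, 0.1), π_i = q_i1·0.9 + q_i2·0.1, and G_i ~ Binomial(2, π_i).  The
phenotype is Normal(β·g + γ·q₁, 1) (γ = 1 in structured presets; a binary
option passes the same predictor through a logit).  Sequencing depth takes
one of two levels (1X, 4X by default, Poisson read counts, read error
ε = 0.01): with depth–phenotype correlation δ, individuals in the top half
of the phenotype ranks draw the high level with probability 0.5 + δ/2 and
the rest with 0.5 − δ/2, so δ = 0 is independence and δ = 1 a deterministic
split.  The six named presets cover the crossings of genotype effect,
structure and depth correlation; "correlated" presets default to δ = 0.5.

The exact depth-assignment law, admixture law and read-error rate of the
original study are not published; the versions above are this package's
choices, kept behind the config objects so they can be revised without
touching the estimators.  Consequences of the difference are noted below.

### Case-control design

A disease with prevalence K and per-allele relative risk r: p(case | g) =
k·r^g with k solved so Σ_g HWE(f)_g·k·r^g = K (infeasible risks > 1 are
rejected).  Cases are drawn from p(g | case) ∝ HWE(f)_g·r^g, controls from
the complementary conditional; cases get mean depth 4X, controls 1X
(presets), and zero-read individuals are dropped or kept per design.
Defaults mirror the published study: 50,000 + 50,000, f = 0.05, K = 0.10.

Because case-control sampling identifies the log odds ratio rather than
log(r), the *bias* column of power tables is measured against the
asymptotic true-genotype logistic slope (computed exactly from the six
(status, genotype) cell probabilities); log(r) is reported separately.

### Power experiments

`run_power_experiment` spawns one seed stream per replicate from the master
seed (results are bit-reproducible), simulates a fresh site and cohort per
replicate, runs each requested method (true-genotype GLM, dosage, latent,
score, hybrid), and tabulates power (fraction of p ≤ α), mean/SD of β̂,
bias, mean SE, per-stratum info measures and fit-failure counts.  Unless
told otherwise it uses the *estimated* sample-frequency prior — the
realistic condition, since the true frequency is never known; a
`prior` switch selects the true frequency, or individual-frequency priors
with true or estimated population frequencies (admixture always known).

## What the synthetic data does and does not show

The generator reproduces the mechanisms the estimators are sensitive to —
genotype uncertainty growing as depth falls, depth differing by phenotype or
case status, ancestry-dependent allele frequencies — but not haplotype
structure, LD, imputation-panel effects, relatedness, or per-base quality
variation.  Passing tests therefore demonstrate correctness of the
estimators and the direction/order of the published effects, not their exact
magnitudes on real data.

Three published magnitudes deserve explicit caveats.  With this read model
the control-stratum (1X, zero-read individuals removed) info measure
computes to ≈0.47–0.50: a single read can reveal at most one of the two
allele copies, which caps the dosage-variance ratio near 0.5 at depth ~1, so
the published 0.85 cannot arise from a per-site binomial read model and must
reflect a different (unpublished) simulation detail.  Relatedly, the dosage
and latent powers in the depth-biased design land near 0.45–0.60 rather
than the published 0.431/0.659 — the orderings (latent ≥ dosage in power,
latent less biased) hold robustly and are what the tests assert.  Finally,
under the symmetric admixture law used here (uniform q, frequencies
0.9/0.1), the sample-frequency prior in the structured null scenario biases
β̂ clearly downward but does *not* measurably inflate the false-positive
rate: the depth-dependent shrinkage error is an odd function of π − ½ and
cancels in the slope after ancestry adjustment.  An asymmetric admixture or
depth law breaks the cancellation; the published inflation presumably arises
from such a law.

## Numerical choices and edge cases

* Tolerances: EM |Δ loglik| < 1e-6 (fits), |Δf| < 1e-8 (sample AF),
  |ΔF|∞ < 1e-6 (population frequencies); inner IRLS 1e-8; finite-difference
  steps 1e-5·max(1, |θ|) (gradient differencing), with the σ² step capped at
  σ²/2 to stay positive.
* Minor-allele coding is taken from the input file and never re-polarized by
  frequency, so effect signs are deterministic.
* BEAGLE triplets are renormalized on load if their sum is within
  [0.9, 1.1], rejected with a line number otherwise.  Sample order across
  files is positional.
* The MAF filter (default 0.005) applies to the frequency actually used as
  the prior.  No multiple-testing correction is applied; raw p-values are
  reported.
* Individuals with missing phenotype/covariates are removed listwise before
  fitting; zero-read individuals are kept unless the caller excludes them.
* Test problem sizes: power/calibration tests use 300–2,000 replicates with
  3-binomial-SE Monte-Carlo bands at the count used; the acceptance script
  uses 500 replicates for true-genotype powers, 300 for dosage/latent
  powers, 2,000 for the null rejection rate and 50 for the info measure.
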