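# Methods

## Model and assumptions

Each gene, in each biological condition, is treated independently. Counts
are assumed conditionally independent across cells given the design, with
mean linked to the linear predictor through a log link and a library-size
offset: log mu_j = x_j' beta + log N_c. The offset coefficient is fixed at
1, so depth normalization is part of the model rather than a preprocessing
transform. Natural log is the default offset scale; base-10 is available
(`offset_base: "10"`) but note that with a log-link model only the natural
log keeps the interpretation "expected count proportional to depth" with
unit coefficient.

The four candidate families are nested: P ⊂ NB (phi → ∞ recovers Poisson)
and P ⊂ ZIP, NB ⊂ ZINB (omega = 0 recovers the unimodal law). omega is a
single scalar per gene and condition — the zero model is intercept-only —
so it is directly interpretable as the structural-zero proportion.
Covariates act on the count mean only.

## Fitting

P is fitted by IRLS (statsmodels GLM); NB, ZIP and ZINB by quasi-Newton
maximum likelihood (statsmodels discrete models), warm-started from their
nested base fit. Two safeguards matter in practice:

* **Boundary solutions.** On equidispersed data the NB dispersion MLE sits
  on the phi → ∞ boundary, and without zero inflation the ZI MLE sits on
  omega = 0; generic optimizers stall slightly *below* the boundary
  likelihood. Whenever a larger family's fitted log-likelihood falls below
  its nested base fit — impossible for a true MLE — the boundary solution
  (the base fit, relabeled, with phi = inf or omega = 0) is returned
  instead. This keeps the nesting invariant loglik(ZINB) ≥ loglik(NB) ≥
  loglik(P) exact and makes the boundary LRT statistic a clean 0.
* **Divergent quasi-Newton steps.** BFGS occasionally runs to NaN from
  rough starts on strongly inflated genes; a Nelder–Mead pass seeded from
  the same start, followed by a BFGS polish, recovers the interior optimum.

Convergence tolerance is 1e-8 with at most 200 iterations; non-converged
families are excluded from model selection for that gene rather than
failing the gene. Every fit's log-likelihood is validated in the test
suite against brute-force summation of per-cell log pmf values (1e-6).

## KS family gate

The gate fits the covariate-free ZINB marginal by maximum likelihood
(L-BFGS-B over logit pi, log mu, log theta with analytic gradients, data
compressed to unique-value/multiplicity pairs) and measures D = sup_k
|ECDF(k) − CDF(k)| over the integer support. Because the parameters are
estimated, the null distribution of D comes from a parametric bootstrap
that *refits* the marginal on every simulated replicate; the add-one
estimator p = (1 + #{D_b ≥ D_obs})/(n_boot + 1) keeps p > 0. Defaults:
n_boot = 199 in tests and 999 in production runs, BH adjustment within
condition, and retention when the adjusted p ≥ alpha = 0.01 (the gene is
retained when the ZINB family is *not* rejected). These three constants
are package choices, configurable in `RunConfig`. Note that removal at
level alpha requires 1/(n_boot+1) < alpha, i.e. at least 100 replicates
for alpha = 0.01.

The gate's type-I error is calibrated (≈ 5% rejection at p < 0.05 on
in-family data) and it has strong power against laws outside the family
(bimodal mixtures and discretized heavy-tailed laws are rejected
essentially always at n = 1,000).

## Selection and adequacy

The candidate is the least-BIC family among converged fits, ties broken
toward the simpler family in the order P < NB < ZIP < ZINB. Two rounds of
adequacy testing follow. Round 2 (decision-making): a zero-inflated
candidate must pass the boundary LRT against its unimodal counterpart at
alpha = 0.05; the null is the equal mixture 0.5·chi²₀ + 0.5·chi²₁ because
omega = 0 lies on the parameter-space boundary, so p = 1 when the
statistic is 0 and half the chi²₁ tail otherwise. Failure demotes the call
to the counterpart. Round 1 (diagnostic): unimodal calls record a deviance
goodness-of-fit p-value against the saturated model (NB saturated
log-likelihood holds the fitted phi fixed, standard practice); it triggers
no relabeling because no principled fallback exists for unimodal
inadequacy. The deviance test is not valid for zero-inflated fits (the
models are not strictly nested) and is not applied to them.

A consequence worth knowing: a zero-inflated family can only win BIC over
its counterpart when the LRT statistic exceeds ln n, so at alpha = 0.05
the LRT fallback binds only for very small n or stricter alpha — it is a
guard rail, not a frequent event.

## Differential distribution

A gene is differentially distributed when its labels differ across the
compared conditions; the call is a label change, not a significance test
on the switch itself. Genes FAILED in a compared condition are excluded
from that comparison only. Switch categories follow the partition
unimodal {P, NB} vs zero-inflated {ZIP, ZINB}. For zero-inflated genes the
report includes omega_hat, the observed zero fraction, the model zero
probability and the derived ratio omega_hat / P(Y=0) — the share of the
observed zeros attributed to structure.

## Synthetic data

The generator emulates filtered droplet data: per-cell depth N_c
log-normal (meanlog = ln 3000, sdlog = 0.35, a typical 10X spread) or
resampled from an empirical vector; each gene intercept-only with mean
exp(beta0)·N_c, so all genes share a cell's depth draw. Default parameter
ranges: mean expression exp(beta0)·E[N_c] log-uniform in [0.5, 20], phi
log-uniform in [0.3, 5], omega uniform in [0.1, 0.7]. The drawn depth is
recorded as the cell's library size; recomputing depth from a small
simulated gene panel would add offset measurement error that shows up as
spurious overdispersion.

What the generator does **not** emulate: gene–gene correlation, cell-type
mixture structure, batch effects, ambient RNA, or mean–dispersion trends
across genes. Passing recovery tests therefore demonstrate correctness of
the estimation and selection machinery under the model, not robustness to
real-data violations of it.

## Problem sizes in the shipped tests

Simulation-based tests are sized to run comfortably on one CPU: label
recovery uses 60 genes per family at 3,000 cells (accuracy threshold 0.85
per family, unchanged); KS retention uses 25 genes per family at 500
cells; LRT null calibration 400 genes; parameter recovery 8 replicates per
family at 5,000 cells; DD false-switch control 25 genes per family at
1,000 cells in two conditions; the sample-size monotonicity check 25 genes
per family over n ∈ {1000, 3000, 5000} across 5 seeds. The acceptance
script uses 100 genes per family. Larger runs only tighten the Monte-Carlo
error around the same quantities.

## Numerical conventions and edge cases

* 0·log 0 := 0 in saturated log-likelihoods; pmf at mu = 0 is the point
  mass at zero.
* Marginal-fit bounds: pi ∈ [~1e-6, 0.999] (snapped to exactly 0 below
  1e-5 and when no zeros are observed), theta ∈ [0.01, 1e4].
* The pre-screen ratio is +inf (flagged) when zeros are observed but none
  are predicted, and 0 (flagged, overfit direction) when no zeros are
  observed.
* Degenerate genes (constant counts) fail the KS gate and are excluded;
  any per-gene failure degrades that gene to FAILED without aborting the
  run.
* Per-gene Monte-Carlo seeds derive from the master seed and a CRC-32 hash
  of "condition:gene", so results are independent of gene order and worker
  count.
* Kernel subsampling uses a Gaussian KDE with Scott's-rule bandwidth over
  log10 depth; weighted sampling without replacement is sequential draws
  with renormalization. Proportion subsampling rounds quotas by largest
  remainder.

## Known limitations

* ZINB sensitivity is inherently limited for low-mean genes: when the NB
  component already explains most zeros, omega is weakly identified and
  the LRT correctly withholds the zero-inflated label. Expect ZINB
  sensitivity well below its specificity at ≤ 1,000 cells.
* The deviance diagnostic is asymptotic and conservative for small counts.
* Covariates enter the count mean only; a covariate-dependent zero model
  is out of scope.
* The KS gate uses the marginal distribution without covariate or offset
  adjustment; strong covariate effects inflate the marginal dispersion and
  are absorbed by theta rather than rejected.
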