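# Methods

This note documents the statistical machinery in `germfire`: the models and
their assumptions, the decision rules, the synthetic-data generator used for
validation, numerical choices, and known limits.

## Dish-level model

The unit of observation is one Petri dish. Germination is always analysed
relative to *viable* seeds `V_i` (the data model takes `V_i` as given; it
does not adjudicate whether viability was fixed at sowing or finalised
during the test). The likelihood is binomial with a logit link:

    G_i ~ Binomial(V_i, pi_i),   eta_i = logit(pi_i)

Experiment 1 (full 2×2 factorial of heat H and smoke S) uses
`eta = b0 + b1*H + b2*S + b3*H*S`; experiment 2 (combined cue only) uses
`eta = b0 + b1*HS`. Per-treatment probabilities are deterministic functions
of the coefficients (`pi_HS = expit(b0+b1+b2+b3)` etc.), so posterior draws
for them and for any contrast come free with the coefficient draws.

**Priors.** Normal(0, 10²) on every coefficient by default — effectively
flat over any plausible logit. When any treatment cell sits on the boundary
(pooled counts 0% or 100% germination: complete separation), the likelihood
no longer identifies the corresponding coefficient and flat priors let it
drift; the fit then uses Student-t(3, 0, 2.5) priors on all coefficients,
the standard weakly informative remedy. Separation is detected from the
data up front, and a flat-prior fit on separated data carries an explicit
warning recommending the t-prior refit. Exact prior hyperparameters are a
package choice; results for interior cells are insensitive to them.

**Overdispersion.** Dish-to-dish heterogeneity beyond binomial noise is
modelled, when needed, by an observation-level random effect
`eps_i ~ N(0, sigma²)` added to `eta_i` (a binomial GLMM). One shared
`sigma` is used for all dishes of a species — a per-dish variance would be
unidentifiable with one observation per dish. `sigma` gets a half-Normal(2)
prior. Population-level treatment probabilities from the GLMM are reported
at `eps = 0`, i.e. for the median dish; this conditional (rather than
marginal) convention keeps the GLM and GLMM `pi` scales comparable and is
stated wherever the numbers surface.

**The need for the GLMM is decided by a posterior predictive check.** The
discrepancy is the dispersion statistic `T = sum_i (G_i - V_i*pi_i)² /
(V_i*pi_i*(1-pi_i))` (sum of squared Pearson residuals). For each retained
draw, replicate counts are simulated from the fitted model and the Bayesian
p-value is `Pr(T_rep >= T_obs)`; p below 0.05 (overdispersion) or above
0.95 (underdispersion) triggers the GLMM refit. Both fits are retained in
reports. For the GLMM the check conditions on the sampled dish effects.

## MCMC

The sampler is adaptive random-walk Metropolis-within-Gibbs, vectorised
across independent chains:

* a full-covariance block proposal for the coefficients, with the proposal
  covariance re-estimated from the burn-in history every 250 iterations and
  a Robbins–Monro step-size adaptation targeting 28% acceptance;
* element-wise proposals for the dish effects (conditionally independent
  given coefficients and `sigma`), targeting 44% acceptance;
* a scalar random walk on `log sigma` (with Jacobian), half-Normal prior.

All adaptation stops at the end of burn-in, so retained draws come from a
fixed, valid Markov kernel. Chains start from jittered empirical logits.
Everything is driven by one `numpy` generator seeded from the
configuration, so identical configurations reproduce draws bit-for-bit on a
platform.

The shipped default protocol is 5 chains × 80,000 iterations, 50,000
burn-in, thinning 10 → 15,000 retained draws, matching the reference
protocol for this analysis; these four-to-six-parameter models converge
far faster, and the test-suite and validation runs use a few thousand
iterations. Convergence is declared when all split-chain Gelman–Rubin
statistics are below 1.1; non-convergence is flagged on the result object,
never silent. Effective sample sizes use FFT autocovariances averaged
across chains with Geyer's initial-monotone-positive truncation (checked
against the AR(1) closed form and against `arviz` in tests).

## HDI + ROPE decisions and syndromes

* **HDI**: the shortest window over the sorted draws containing
  `ceil(0.95*n)` of them. This is exact for the draw vector (tested against
  an exhaustive window scan) and correct for unimodal posteriors.
* **Mode**: argmax of a Gaussian-kernel KDE evaluated on a 512-point grid
  clipped to the parameter's support. The bandwidth is Silverman's constant
  with the `n^(-1/7)` rate that is optimal for mode (not density)
  estimation: flat-topped posteriors such as Beta(2, 4) make the argmax of
  a density-optimal KDE wobble by several hundredths across seeds, and the
  extra smoothing removes most of that variance at negligible bias
  (verified against analytic kernel-convolution modes). Reflection at the
  support boundary was deliberately *not* used: it forces the mode of any
  monotone posterior (e.g. a 7/7 cell) to the boundary exactly, which
  misrepresents where the smoothed density peaks.
* **ROPE verdicts**: an effect (percentage-point contrast vs. control) is
  trivial if its 95% HDI lies within [−10, +10], non-trivial if disjoint
  from it, uncertain otherwise. Both the overall posterior mass outside the
  ROPE and that mass restricted to draws inside the HDI are reported; the
  restricted version operationalises statements like "94.9% of the HDI
  outside the ROPE" as posterior mass, the natural Bayesian reading.
* **Control**: classified against a [0%, 50%] ROPE, with the exceedance
  probability `p_C = P(pi_C >= 0.5)` reported.

**Syndrome rule.** The four-way call formalises a narrative classification;
the thresholds are this package's explicit formalisation, exposed in
configuration. With `tau = 0.85` (chosen because ~85% probability of
control germination ≥ 50% is the boundary of the fire-enhanced group) and
`p_t = P(pi_t >= 0.5)` per cue treatment:

* **FD** — some promotive cue effect non-trivial, `p_C < 1 - tau`, and some
  treatment reaches `p_t >= tau`;
* **FE** — some promotive cue effect non-trivial and `p_C >= tau`;
* **FI** — every cue effect trivial and `p_C >= tau`;
* **FU** — otherwise; species unlikely to reach 50% germination under any
  treatment are additionally annotated "low overall germination".

The rule is exhaustive and mutually exclusive by construction. Widening the
ROPE can only move verdicts toward trivial/uncertain (tested as a
property).

## Prevalence comparisons

Each 2×2 table (species with/without an effect × trait group) is analysed
with independent Beta posteriors under uniform Beta(1, 1) priors:
`theta_g ~ Beta(x_g + 1, n_g - x_g + 1)`. The group difference is the
paired Monte Carlo difference of draws; summaries are KDE modes, 95% HDIs
and the probability of direction `P(theta_1 > theta_2)`. The uniform prior
is verifiable against the printed intervals analytically: a 7/7 cell gives
Beta(8, 1), whose monotone density puts the 95% HDI at `[0.05^(1/8), 1] ≈
[0.688, 1]`. 200,000 draws per group keep mode and HDI estimates stable to
roughly ±0.01 even against support boundaries. Species whose cue status is
uncertain are excluded from the tables (a configuration flag can instead
code them as no-effect), and "fire effect" means a non-trivial *promotive*
heat and/or smoke effect; for combined-cue designs the heat+smoke contrast
stands in.

## Phylogenetic signal

Blomberg's K treats the 0/1 response trait as numeric — common practice for
this statistic — and uses the tree covariance matrix `V` (shared
root-to-MRCA branch length). With GLS ancestral mean
`a = (1'V⁻¹x)/(1'V⁻¹1)`:

    K = [MSE0 / MSE] / [(tr V - n/(1'V⁻¹1)) / (n - 1)]

where `MSE0 = (x-a)'(x-a)/(n-1)` and `MSE = (x-a)'V⁻¹(x-a)/(n-1)`. K = 1
matches the Brownian-motion expectation on the tree (and is exactly 1 on a
star phylogeny, where `V` is proportional to the identity). The
implementation agrees with R `phytools::phylosig` to ~1e-7 on test
fixtures. Significance uses tip-label shuffling with
`p = (#{K_perm >= K_obs} + 1)/(n_perm + 1)`, one-sided for signal, default
999 permutations — the permutation count and the p-value convention are
package choices. Ultrametricity is checked and reported but not required.
Taxon surrogation (relabelling tips to stand in for unsampled species)
preserves topology and branch lengths and refuses label collisions.

## Synthetic-data generator

The generator mirrors the model it validates: per treatment a true `pi`,
per dish an optional logit-scale effect `eps ~ N(0, dish_sd²)`, then
`G ~ Binomial(V, expit(logit(pi) + eps))`. Defaults follow the study
design: five replicate dishes of 50 seeds per treatment (25-seed dishes
representable), four treatments for experiment 1, two for experiment 2,
and optional binomial viability thinning. The archetype library spans the
four syndromes with probabilities matched to the observed group profiles —
fire-dependent control 5–10% with a ≥ +65-point cue effect, fire-enhanced
control ≈ 62% with a +33-point smoke effect, fire-independent ≈ 97%
everywhere plus a fully separated 100%-everywhere variant, an uncertain
archetype whose true effect (+10 points) sits on the ROPE boundary, an
experiment-2 design, and an overdispersed variant (dish SD 0.75).

Trees come from a unit-rate Yule process (ultrametric by construction);
traits from Brownian motion along branches. These support the K
calibration: mean K ≈ 1 over replicate BM simulations, uniform permutation
p under a shuffled null.

What the generator does *not* emulate: germination time-courses, fungal
seed loss during incubation, between-experiment batch effects, non-logistic
dose responses, and correlated dish effects within treatments. Passing the
recovery tests therefore shows the inference machinery is calibrated for
data satisfying the model's assumptions, not that real trials satisfy them
— that is what the posterior-predictive checks are for on real data.

## Validation design and problem sizes

The test suite validates each stage against an independent route: conjugate
Beta posteriors for intercept-only fits, exhaustive window scans for the
HDI, analytic Beta moments/quantiles for the prevalence comparisons, path-sum
oracles and `phytools` for the tree statistics, closed forms for ESS on
AR(1) draws. Calibration experiments use 200 simulated species for HDI
coverage (2 chains × 2,000 iterations each — these posteriors are
effectively four independent binomial cells, for which short chains
suffice), 15 replicate runs per archetype for label recovery, 200 Brownian
replicates on 40-tip trees for the K mean, and 500 replicates × 199
permutations for p-value uniformity. The diagnostics check runs the full
scenario library at the reference protocol scaled down tenfold (5 chains ×
8,000 iterations, 5,000 burn-in, thinning 10).

## Known limitations

* The coefficient sampler is a random-walk method: adequate and fast for
  these 2–4 coefficient models (plus ≤ 20 dish effects), but its effective
  sample size per iteration is well below gradient-based samplers'; very
  long protocols are needed to reach five-figure ESS.
* KDE modes near a support boundary depend on the bandwidth convention;
  the one used here is documented above and applied uniformly.
* The FD/FE boundary depends on `tau`; species with `p_C` between
  `1 - tau` and `tau` and a non-trivial effect are deliberately left FU.
* K on binary traits is a pragmatic convention; no threshold-model
  alternative is provided.
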