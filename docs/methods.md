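# Methods

## Ordinal outcome and scores

BODN counts the bodily systems with at least one disease above the healthy
reference level (code 1). With `K` systems the outcome takes values
`0…K`; the cumulative model therefore carries `K` thresholds over `K+1`
categories. The alternative reading — categories starting at 1 — is a strict
subset (the bottom category is simply never observed) and needs no separate
code path.

The frailty index expands every non-reference severity level of every
disease into one binary deficit item and reports the proportion present; an
individual at level `x` of a disease holds `x − 1` of its items. This makes
FI = 0 exactly when BODN = 0 and mirrors the usual deficit-accumulation
construction in which, e.g., each distinct eye condition is a separate item
while the ordinal codex treats them as levels of one condition.

Lagged frames support three anchors: `lag1` (rolling visit pairs, the
default), `baseline` and `second_visit` (predictors frozen at the first or
second visit for all later outcomes). The time covariate is years from the
anchor visit to the outcome visit. Individuals without a valid
predictor/outcome pair are dropped with a warning, not an error.

## The cumulative-monotonic model

Logit link throughout (the cumulative-family default in the R lineage this
model class comes from; probit/cloglog are out of scope). A disease's
monotonic term is `b_d · Σ_{j<level} ζ_{d,j}` with `ζ_d` a simplex over the
`D_d − 1` level transitions, so `b_d` is the *total* level-1→level-`D_d`
effect. The per-step convention used by some packages (coefficient = average
step, total = b·(D−1)) converts by dividing/multiplying by `D_d − 1`.

Weakly-informative priors: thresholds Student-t(3, 0, 2.5) on their natural
scale (with the log-increment transform keeping them ordered), `b_d` ~
Normal(0, 2), `ζ_d` ~ Dirichlet(1,…,1) (parameterized by log-Gamma(1,1)
variables), linear coefficients Normal(0, 2), `σ_u` ~ half-Student-t(3, 0,
2.5). The individual term is a single random intercept per person.
Chronological age never enters a clock-producing model (asserted
structurally in the pipeline); it appears only as the outcome of the age
regressions and as a covariate of the explicitly labeled age-only
comparison model.

Zero-variance severity predictors are dropped with a warning. A single
observed outcome category is a hard error.

### Sampling

No pre-installed package fits this model class, so the sampler is part of
the package: adaptive Metropolis-within-Gibbs with three move types per
iteration —

1. coordinate-wise random-walk updates of the unconstrained global vector,
   scales adapted toward 0.44 acceptance during warmup;
2. joint adaptive-Metropolis proposals using the online warmup covariance
   (targeting 0.23 acceptance), which handle the strong threshold/effect
   correlations;
3. a vectorized Metropolis sweep over *non-centered* standardized intercepts
   `v = u/σ_u` (their conditional posteriors are independent given the
   globals), followed by an interweaved centered update of `σ_u` given the
   actual intercepts — a prior-only Metropolis move that removes the funnel
   between the intercepts and their scale.

Defaults: 2 chains, 800 warmup + 1500 kept draws, 3 intercept sweeps and 6
joint updates per iteration. Convergence is checked per parameter with
rank-normalized split R-hat ≤ 1.01 and bulk ESS ≥ 100 (arviz); failing
either flags the fit (`converged=False`, with a warning) rather than
erroring — reduced-draw runs inside simulation studies deliberately accept
the flag. Pointwise log-likelihoods are stored per kept draw for LOO.

Prediction for individuals seen in training reuses their intercept draws;
new individuals draw intercepts from Normal(0, σ_u) per posterior draw
(`group_mode="population"` forces this marginal treatment for everyone,
which transfer prediction uses). The clock summary is the posterior mean of
the per-draw expected category `Σ_k k·P(Y=k)` (a continuous value in
`[0, K]`); the median is available as an option.

## Auxiliary regressions

* **Gamma age models** (`age ~ clock`, log link): mean `exp(a + b·x)`, shape
  with an Exponential(0.1) prior, coefficients Normal(0, 10)/Normal(0, 2.5).
  Sampled with emcee (32 walkers); posterior predictions are per-row means
  of `exp(a + b·x)` with no upper ceiling. Worked-example reporting rounds
  half away from zero to 2 decimals.
* **Walking speed**: Gaussian with mean `b₀ + b_c·clock + b_h·height` and
  `log σ = g₀ + g_c·clock`; height is required. The Speed-Body Clock is the
  posterior-mean predicted speed in m/s.
* **Disability (ZIBB)**: `p(y) = π·1{y=0} + (1−π)·BetaBinomial(y | n, μφ,
  (1−μ)φ)` with `n = 47` trials by default, `logit μ` an intercept plus an
  optional Body Clock term and optional per-individual intercepts. Priors:
  coefficients Normal(0, 2), π uniform, φ Exponential(mean 25). The
  Disability Index is the posterior-mean predicted event *proportion*
  (in (0,1)); the Disability-Body Clock is the posterior-mean predicted
  *count* (in [0, 47]), matching the scales on which the two quantities are
  reported. All-zero outcomes fit fine (the inflation component absorbs
  them) and are flagged.
* **Binary endpoints**: person-period negative-binomial counts with a log
  exposure-time offset (a discrete-time hazard approximation); the
  exponentiated clock coefficient is the hazard ratio with a 95% credible
  interval. Exposure doubling is absorbed by the intercept, leaving the HR
  invariant.

## Model evaluation

PSIS-LOO smooths each observation's importance ratios with a generalized
Pareto tail fit (the standard tail fraction, via `arviz.psislw`); the
package assembles pointwise elpd, totals, standard errors and the fraction
of Pareto k < 0.7. ELPD differences use the pointwise-difference variance.
Stacking weights maximize `Σ_i log Σ_k w_k exp(elpd_ik)` over the simplex by
deterministic convex optimization (softmax parameterization started from the
barycenter, analytic gradient); exactly symmetric inputs therefore return
equal weights. The function is agnostic to the grouping: weights can be
computed per model pair (each candidate against its age-only counterpart, the
reporting convention used for the comparison tables) or jointly across any
number of candidates. Posterior predictive checks compare observed category
frequencies against replicated ones with a total-variation discrepancy and a
95% replicate band. AUC is the midrank statistic (probability a random
positive outranks a random negative).

## Synthetic cohorts

`generate_cohort` emulates a longitudinal aging study: baseline ages uniform
over a configurable range (default 40–85), visits at fixed spacing (default
2 years), ~26 diseases in 13 systems with 2–5 ordered severity levels.
Severity progression is monotone (chronic accumulation, no remission): each
disease advances at most one level per year with probability
`expit(step_logit_d + 0.5·(age−55)/10 + log r_i)`, where `r_i` is a
log-normal per-individual aging rate (default SD 0.45 on the log scale).
Default step logits (mean −4.6) put the baseline mean BODN near 2 at ages
40–50 rising to ~8 at 80+, with within-band variance increasing with band
age — the heightened-heterogeneity pattern of aging cohorts.

Outcomes couple to a latent **weighted system burden** on the BODN scale:
disease levels map to burden fractions through a per-step simplex whose
first transition carries most of the weight by default
(`first_step_share = 0.6`; mild states matter most, the pattern reported
for, e.g., untreated hypertension and subclinical hypothyroidism), fractions
combine within a system by a saturating probabilistic-OR, and systems
combine with log-normal weights. Walking speed declines by `speed_slope`
(default −0.05 m/s, within the reported 0.03–0.065 band) per burden unit;
disability counts are ZIBB (47 trials, π = 0.3, φ = 10, logit-linear mean in
the burden); mortality is a piecewise-constant hazard `h₀·exp(log HR ·
burden)` with default log HR = log 1.8 per unit. Ground truth (latent rates,
generation weights, simplices, slopes) is exported as a JSON sidecar, never
merged into the panel.

`simulate_cumulative_frame` instead draws outcomes directly from the
cumulative-monotonic likelihood with i.i.d. uniform severity levels — the
tool for parameter-recovery and calibration experiments, where the recorded
truth is the model's own parameter vector.

**What passing tests show, and what they do not.** The generator reproduces
the *structure* the analysis assumes — monotone progression, rate
heterogeneity, weighted-burden couplings, ZIBB disability, hazard-scaled
mortality — but not real disease epidemiology: incidence rates are not
calibrated per condition, severities never remit, visits are equally spaced,
and measurement error in disease ascertainment is absent. Recovery and
directional results on these cohorts validate the implementation and the
internal logic of the metrics, not their clinical performance.

## Study conditions of the headline experiments

Problem sizes were chosen so each experiment isolates its mechanism at
desk scale.

* *Parameter recovery*: n = 600 individuals × 3 visits, 3 three-level
  diseases with effects (1.2, 0.8, −0.5), thresholds (−1, 0.5, 2), time
  coefficient 0.1, σ_u = 0.5; 20 replicates at reduced draws; 90% credible
  intervals must cover each true maximum effect in ≥ 80% of replicates.
* *ELPD ordering (full vs. age-only)*: the full model's advantage is
  tracking heterogeneous progression *speed*, so the scenario uses purely
  rate-driven progression (no direct age effect on transitions), high rate
  spread (0.8), 6 systems, 6 visits × 2.5 years, enrollment at 40–70; the
  pooled ELPD difference over three replicates must favor the full model.
* *Clock vs. FI (AUC)*: asymmetric disease counts per system (4/1/2/1) and
  strongly concave level effects (`first_step_share = 0.85`) — the two
  regimes where an equal-weight deficit count mis-ranks by construction —
  with endpoint couplings strengthened (φ = 25, π = 0.15, burden slope 0.5,
  base hazard 0.03) so endpoint noise does not swamp the comparison; mean
  AUC over three replicates per endpoint.
* *Transfer prediction*: two 250-individual cohorts from the same generator;
  the train-on-A/predict-on-B clock must correlate r ≥ 0.7 with the natively
  refit clock.

## Numerical choices and degenerate inputs

Ordinal category probabilities are logistic-CDF differences clipped at
1e-300 before logs. Thresholds are sampled as (τ₁, log-increments) with the
Jacobian in the prior. Simplices use the Gamma(1,1)-normalization
parameterization; the binary-disease case (`D = 2`) pins ζ = (1). Ties in
ROC scores use midranks. Stacking's flat directions (identical models)
resolve to the barycenter by construction. `predict_age` rejects non-finite
linear predictors; Gamma fits reject non-positive ages; ZIBB rejects
`y > n`. Fits serialize to `.npz` archives with a JSON header (codex content
hash included) so a fit trained on one panel can score another; a codex
mismatch is an error.

## Known limitations

Threshold effects are proportional (no category-specific effects); only the
logit link is implemented. The hand-rolled MCMC is tuned for the model
sizes used here (tens of global parameters, hundreds of groups); very large
codices will sample slowly and may need more draws to clear the convergence
thresholds. PSIS-LOO with per-individual intercepts is conditional on the
intercepts, so "leave one observation out" shares individual information
across that individual's other visits — the standard behavior of pointwise
LOO in multilevel models, but not equivalent to leave-one-*person*-out.
The discrete-time hazard approximation reports rate ratios as hazard
ratios; with long intervals and high hazards the two diverge.
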