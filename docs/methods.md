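# Methods

## Task model

The IMT session is a factorial grid: control condition (extrinsic,
intrinsic) × valence (win, loss) × outcome type (money, social) × outcome
magnitude.  Defaults follow the published design where it is stated —
228 trials split evenly over the four valence × outcome-type cells, effort
capped at 70 presses, 30% of trials randomly designated for effort
execution — and make documented choices where it is not:

* **Offered effort levels** (extrinsic trials): 6 equally spaced integer
  levels on [10, 70].  Only the cap is published.
* **Outcome levels**: 8 equally spaced levels spanning $0.25–$2.00 and
  25–200 points.  Only the ranges are published.
* **Extrinsic:intrinsic split**: the published sources disagree (a 228-trial
  total in one place, 224 extrinsic + 64 intrinsic in another; likewise 30%
  vs. "roughly 20%" effort execution).  Defaults follow the primary text
  (228 trials, 3:1 extrinsic:intrinsic rounded within each cell, giving
  172:56; execution fraction 0.30); both are config options
  (`ScheduleConfig`).
* **Trial order**: uniform seeded shuffle, no run-length constraints.

Money and social outcomes are normalized by their scale maxima onto a
common x-axis in (0, 1], so all trials of a valence feed one curve.

## Observation model

The published analysis does not state the likelihood linking a curve to
responses.  We treat the curve value y(x) as the subject's indifference
effort and use the minimal noise models that make both response types
generative from one curve:

* extrinsic: P(accept) = logistic((y(x) − offer)/τ), temperature τ in
  presses;
* intrinsic: reported effort ~ Normal(y(x), σ_obs), in presses, clamped to
  [0, 70] and rounded at simulation time (the likelihood ignores the
  rounding; at σ_obs ≥ ~1 press the discretization error is negligible).

Each condition's fit carries the one noise parameter its likelihood uses
(τ for extrinsic conditions, σ_obs for intrinsic ones), estimated per
subject × condition.  This keeps every fit self-contained; a shared-noise
variant would couple conditions without changing the curve parameters that
the downstream statistics consume.

## Hierarchical fitting

Subject × condition × family fits are MAP estimates in a transformed space
(σ, τ, σ_obs, L, S, A, c on the log scale; sigmoid bias untransformed so it
can sit outside (0, 1) for never/always-motivated subjects; the linear
slope and intercept untransformed).  Optimization is L-BFGS-B with box
bounds and 4 deterministic starts (prior mean ± seeded jitter).  The
posterior covariance is the inverse finite-difference Hessian of the
negative log joint; the log evidence is the Laplace approximation
log p(y|θ̂) + log p(θ̂) + (d/2)log 2π − ½log|H|.  A singular Hessian falls
back to the prior covariance with a logged warning.

The mixed-effects loop replaces the original variational-Bayes toolbox
inversion with the same fixed-form Gaussian family and the same parametric
empirical-Bayes iteration: after each round, the per-condition prior is
re-estimated as (mean of posterior means, between-subject covariance of
means + mean within-subject covariance, floored to SPD), and fitting
repeats until the summed log evidence gains < 0.01 nats or 16 rounds.
Because the prior changes between rounds the summed evidence is not
guaranteed monotone; violations beyond the tolerance are recorded in the
fit trace rather than raised.  Round-1 priors are weakly informative
mid-range heuristics (bias 0.5, σ 0.2, asymptote 0.75·cap, noise 5
presses; diagonal sd 1 in transformed space, wider for the linear family's
untransformed coefficients).

Subjects giving the same button response on every extrinsic trial are
excluded before fitting, mirroring the deterministic-choice exclusion rule
of the original studies.

## Model selection

Random-effects Bayesian model selection treats the family identity as a
Dirichlet-multinomial random effect (flat prior α₀ = 1).  The variational
update iterates assignment responsibilities and concentration parameters to
a fixed point; exceedance probabilities are Monte-Carlo estimates from the
Dirichlet posterior (10⁶ seeded samples by default; MC error ≪ 0.01).  The
Bayes omnibus risk compares the free energy of the random-effects model
against the equal-frequency null, and PXP = EP·(1−BOR) + BOR/K.  Evidence
is summed over the four conditions per subject before comparison (a
per-condition mode is available by filtering the estimates table).

Note one property that is sometimes assumed of this procedure but does not
hold: adding a subject with perfectly uniform evidences does not
necessarily pull the expected frequencies toward uniform, because ambiguous
subjects are assigned in proportion to exp(ψ(α)), which is more extreme
than α/Σα.  The test suite asserts the correct comparative form (a
uniform-evidence subject dilutes relative to an informative one).

## Synthetic cohorts

The generator emulates the study's *structure*, not its numbers: no raw
data are available, so group-mean magnitudes, couplings and noise levels
are free knobs chosen once to give ~0.4 between-subject-SD separations and
detectable, testable effects.  Defaults:

* **Bias** (between-subject sd 0.15): HC means 0.45/0.50/0.55/0.60 for
  extrinsic-win/extrinsic-loss/intrinsic-win/intrinsic-loss (extrinsic
  motivation higher than intrinsic; wins more motivating than losses).
  MDD: +0.06 on extrinsic and +0.06 on loss conditions (lower extrinsic
  and loss-avoidance motivation).  ANX: −0.06 on both (the opposite).
* **Sigma** (sd 0.04): HC 0.10/0.12/0.14/0.16; ANX +0.016 intrinsically
  (outcome insensitivity under intrinsic control).
* **Trait structure**: 59% of bias variance and 35% of sigma variance is a
  subject-level trait shared across conditions.  Fully independent
  per-condition draws would imply near-zero internal consistency across
  the four condition "items", contradicting the reported ordering
  (bias α ≈ 0.89 > sigma α ≈ 0.68); the fractions follow the
  Spearman–Brown relation for alphas of that order.
* **Symptoms**: truncated normal within instrument ranges (TEPS, STICSA,
  PSS, QIDS), group-shifted means, linear Gaussian couplings expressed as
  target correlations on standardized parameter deviations (defaults:
  anticipatory pleasure ↔ extrinsic bias −0.2; consummatory pleasure ↔
  intrinsic sigma −0.3/−0.25).  Truncation slightly attenuates realized
  correlations; the tolerance is the Fisher-z CI at the cohort size.
* **Reaction times**: lognormal, log-scale offsets +0.5 for intrinsic
  control, +0.05 for losses, +0.08 MDD / −0.08 ANX, residual sd 0.3,
  base 1.2 s.  This reproduces the reported ordering (intrinsic slower;
  MDD slowest, ANX fastest).

What passing tests on these cohorts do **not** show: that the pipeline
reproduces any published F statistic or correlation magnitude; that real
participants satisfy the logistic/Gaussian observation model; or that
symptom couplings are linear.  They show that under the assumed generative
structure the pipeline recovers known parameters, selects the generating
family, and detects effects of the encoded direction and size.

## Statistics

* RM-ANOVA uses the classical univariate sums-of-squares route implemented
  via within-subject contrast scores and an effects-coded (sum-to-zero)
  between-group design, i.e. Type-III-style unweighted marginal means under
  unbalanced groups.  With 2-level within factors sphericity holds
  automatically, so no Greenhouse–Geisser correction is implemented.  Error
  df is N − g for every within effect (178 at N = 181 with 3 groups; 257 at
  N = 258 ungrouped).
* Tukey(-Kramer) post-hoc contrasts use `scipy.stats.studentized_range` on
  subject-level means.
* Partial correlations residualize both variables on the covariates (age;
  sex and medication as binary indicators) and use t with n − 2 − k df.
* The dependent-correlation test is the Meng–Rosenthal–Rubin Z for two
  correlations sharing one variable; p is one-sided by default (the
  published pairs imply one-sided reporting), with a two-sided switch.
* Scale-wise Bonferroni over the four conditions gives the 0.0125
  threshold.
* Paired t tests adopt conventions at zero difference variance: t = 0
  (p = 1) for identical sessions, ±∞ (p = 0) for a pure shift.

## Problem sizes and numerical choices

Test and acceptance runs use scaled cohorts chosen as the smallest sizes at
which each claim is stable: parameter recovery and reliability on 40
subjects × 228 trials (6 empirical-Bayes rounds), three-family model
selection on 30 subjects (3 rounds), detection power on 50 replicates of
the full 74/63/44 cohort drawn at the parameter level (the interactions are
properties of the generator, not of the curve fits, so no fitting is needed
there).  Convergence tolerance 0.01 nats; Hessian steps 10⁻⁴·max(1, |θ|);
SPD floors 10⁻⁸ (posteriors) and 10⁻⁶ (population priors); Dirichlet
updates iterate to 10⁻⁸.  Ties in model attribution break by fixed family
order (linear < sigmoid < weibull) and are flagged.

## Known limitations

* The empirical-Bayes loop estimates the population prior by moment
  matching rather than a full hierarchical marginal-likelihood
  optimization; evidence values are Laplace approximations and inherit its
  quadratic-posterior assumption.
* The intrinsic likelihood ignores censoring at 0 and at the effort cap;
  subjects whose curves hug the cap are better handled by raising the cap
  than by the current Gaussian.
* The generator draws symptom scores independently across scales given the
  parameter couplings; real instruments correlate with each other.
* Group analyses assume one group label per subject and complete
  within-factor crossings; incomplete designs are rejected, not imputed.
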