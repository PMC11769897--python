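# imt — intrinsic vs. extrinsic control of effort-based motivation

`imt` is an analysis pipeline for the **Internal–external Motivation Task
(IMT)**, an effort-based decision-making paradigm that separates two modes
of control over motivated behavior:

* **extrinsic control** — the environment offers an effort level (button
  presses) for an offered outcome and the participant accepts or rejects it;
* **intrinsic control** — the participant self-generates the effort they are
  willing to exert for the same outcomes.

Outcomes are monetary ($0.25–$2.00) or social (25–200 points), wins or
losses, crossed evenly over a 228-trial session with effort capped at 70
presses.  The pipeline targets the questions this design was built for:
do depression and anxiety alter motivation differently under intrinsic vs.
extrinsic control, and which anhedonia sub-domains track which parameters?

## The model

Behavior in every condition (control × valence) is summarized by an
effort-by-outcome discount curve *y(x)* mapping the normalized outcome
*x ∈ (0, 1]* to the willing effort *y* (presses).  Three families are fit:

| family  | form                                   | parameters |
|---------|----------------------------------------|------------|
| linear  | *y = m·x + c*                          | gradient *m*, intercept *c* |
| sigmoid | *y = c / (1 + e^{−(x−bias)/σ})*        | asymptote *c*, shift *bias*, width *σ* |
| Weibull | *y = A·(1 − 2^{−(x·L)^S})*             | asymptote *A*, latency *L*, abruptness *S* |

For the sigmoid — the winning family — **bias** is the outcome threshold for
effort initiation (higher bias = lower motivation, i.e. avolition) and
**σ** is outcome (in)sensitivity (higher σ = flatter curve, weaker
adjustment of effort to outcome changes).

The curve value at *x* is the subject's indifference effort.  Extrinsic
accept/reject choices follow a logistic rule,
P(accept) = 1/(1 + e^{−(y(x)−offer)/τ}), and intrinsic self-set effort is
Gaussian around *y(x)*.  Each subject × condition is fit by MAP with a
Laplace log-evidence within a mixed-effects empirical-Bayes loop: the
population distribution of posterior estimates becomes the prior for the
next round, iterated until the group log evidence stops improving.
Families are compared by random-effects Bayesian model selection, with the
**protected exceedance probability** (PXP = EP·(1−BOR) + BOR/K) as the
headline metric.  Winning-family parameters then enter repeated-measures
ANOVAs (control × valence within, group between), Tukey post-hoc tests,
covariate-adjusted partial correlations with symptom scales (scale-wise
Bonferroni, p < 0.0125) and dependent-correlation Z tests.

No trial-level data are distributed with the study this pipeline models,
so `imt.simulate` generates full synthetic cohorts (three groups, six
symptom scales, covariates, reaction times) whose effect *directions* match
the reported findings; all magnitudes are documented free knobs
(`docs/methods.md`).

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1   # 40-subject scaled cohort
python analysis/02_fit_discount_curves.py --seed 1
python analysis/03_select_model.py --seed 1
python analysis/04_group_symptom_stats.py
python analysis/05_reliability.py --seed 1
```

The fit stage prints per-family convergence and how well the sigmoid fit
recovers the generator's true bias parameters:

```
sigmoid : 6 rounds, group log evidence -8512.6, converged=False
bias recovery (true vs fitted, sigmoid):
  extrinsic-loss  r = 0.978
  extrinsic-win   r = 0.972
  intrinsic-loss  r = 0.954
  intrinsic-win   r = 0.970
```

Model selection identifies the generating family:

```
Bayes omnibus risk = 3.14e-09
sigmoid : freq = 0.919, EP = 1.000, PXP = 1.000, attributed to 39 subjects
winning family: sigmoid
```

and the statistics stage reports, among others, the group-by-control
interaction on bias (`F(2,37) = 8.00, p = 0.0013` on this cohort) — the
synthetic MDD group is less extrinsically motivated and the anxiety group
more, while intrinsic motivation is similar across groups — together with
the partial-correlation battery (e.g. extrinsic-win bias × anticipatory
anhedonia `r = −0.618`, passing Bonferroni) and the dependent-correlation
contrast showing that the anticipatory, not consummatory, anhedonia scale
tracks extrinsic bias (`Z = −2.91, one-sided p = 0.002`).

The same machinery is scriptable through the `imt` CLI
(`imt simulate | fit | compare | stats | run-all | validate`) or the
library API (`imt.task`, `imt.curves`, `imt.simulate`, `imt.fit`,
`imt.bms`, `imt.stats`, `imt.pipeline`).

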