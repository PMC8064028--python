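# Methods

## Task model

The task is a two-option probabilistic reversal bandit with post-decision
wagering.  Option win probabilities take one of two values, `p_low = 0.3`
and `p_high = 0.7`, independently per option, and are piecewise constant in
time.  A session has 160 trials in 3 blocks (blocks matter only for the
bank display in the original task and, here, for previous-trial
conditioning, which never crosses a block boundary).  Bets use an ordinal
1–5 scale mapping to stakes (1, 2, 5, 10, 20); surprise is rated 1–5 from
trial 10 (1-based) onward, so that the first nine trials carry no rating.

### Schedule construction

Three published design constraints cannot all hold exactly in 160 trials,
so the generator enforces them in priority order:

1. inter-reversal intervals drawn from {8, 16} with equal counts, hence a
   designed mean of exactly 12 (seven of each; the last interval is
   truncated at trial 160, and `designed_intervals` keeps the
   pre-truncation draws so the property stays testable);
2. each of the four joint probability combinations occupies exactly 32 of
   the first 128 trials;
3. transition-type coverage is maximized greedily.

Construction is a seeded randomized backtracking search over interval
permutations and joint-state assignments; if the occupancy constraint is
unsatisfiable (e.g. a balance window not divisible by 4) or the attempt
budget is exhausted, an error is raised rather than silently relaxing a
constraint.  Consecutive joint states are required to differ, so every
boundary is a real reversal; identity "transitions" (nothing changes) are
consequently never produced, and coverage is over the 12 changing
transition types.  Option identity is 0/1; colour naming is presentation
only.  Trial indices are 0-based internally, 1-based in all files.

## Generative agent

Learning follows the Rescorla–Wagner delta rule on the chosen option only,
`Q_c <- Q_c + alpha * (R - Q_c)` with `R` in {0, 1} irrespective of the
stake; the unchosen option's value is frozen.  Initial values are
`q0 = 0.5`, the midpoint of the reward scale (the uninformative choice).
Choice is a logistic softmax on the value difference with inverse
temperature `beta`.

The bet is a linear policy on within-session z-scaled signals — chosen
value, unchosen value, previous bet, and a previous-win × stay (+1/−1)
interaction — plus Gaussian noise, so that generative coefficients live on
the same scale as the regression estimates and coefficient-recovery tests
are direct.  Because the z-score of the previous bet depends on the
moments of the bets being generated, sessions are produced by a short
fixed-point iteration on those two scalars; at convergence the bets are an
*exact* linear function of the analysis-side predictors (verified to
machine precision in the tests).  In discrete mode the latent bet is
rounded to the nearest level and clipped to 1–5, which attenuates
recovered coefficients (a property test documents the direction);
coefficient-recovery acceptance checks therefore use continuous mode, as
do the noiseless identification tests.  Surprise is generated from the
within-session z-scored win indicator and its product with z-scored chosen
value, on a scale where 1 = "I knew it!" and 5 = "very surprised" (the
published materials list both orders; this package fixes this one).
Block-initial stay and pre-onset surprise are stored as missing, never
imputed.

### Group presets and calibration

Group phenotypes differ only through the distribution of agent
parameters; the simulation code path is identical.

| parameter | control | unilateral | bilateral | basis |
|---|---|---|---|---|
| bet intercept | 2.63 (sd .87) | 3.55 (sd .70) | 3.76 | published mean bet levels |
| w_chosen | 0.312 | 0.312 | 0.842 | published fixed effects (+0.53 elevation) |
| w_unchosen | −0.089 | +0.001 | −0.089 | published fixed effects |
| w_prev_bet | 0.35 | 0.15 | 0.05 | chosen (see below) |
| w_winstay | 0.10 | 0.10 | 0.40 | chosen (see below) |
| bet noise sd | 0.8 | 0.8 | 0.5 | chosen |
| s_reward | −0.45 | −0.90 | −0.45 | sign/ordering from published asymmetries |
| alpha, beta | 0.3, 5.0 | same | same | calibrated, see below |

The previous-bet and win-stay effect magnitudes are published only as t/F
statistics, so their generative sizes are package choices: large enough to
be detected reliably at the published sample sizes, ordered across groups
as the published contrasts require (controls most biased, unilateral
reduced, bilateral near zero; bilateral win-stay interaction the largest).
The bilateral bet noise is set lower than the other groups because that
phenotype's defining feature is *strategic* betting — wagers that reliably
follow value, visible as winnings that increase steeply with bet level.

Learning parameters are shared across groups (no published group
differences) and were calibrated once against two published behavioural
anchors: a control win rate of ~52% and a choice-model predictive accuracy
of ~77% (simulated: 0.51 and 0.78, per-subject range within 56–99%).
Incompletion rates (controls 7/33, unilateral 9/16, with completion
fractions ~0.90 and ~0.74) mirror the reported attrition.

### What the generator does not emulate

Real participants are not exact Rescorla–Wagner learners.  One visible
consequence: in this generative world any agent whose bets load positively
on chosen value earns a positive bet × p(win) covariance, so simulated
control cohorts win more money (~£60 median per session) than real
controls did (~£14 on average, with flat winnings-by-bet curves).  Passing
recovery tests therefore demonstrates that the *analysis chain* is
unbiased and well calibrated under its assumed data-generating process —
not that real cohorts would show these absolute winnings.  Reaction
times, eye movements and affective state are out of scope.

## Model fitting

Per-subject maximum likelihood on transformed parameters (logit alpha,
log beta), bounds alpha ∈ [0.001, 0.999], beta ∈ [0.01, 50], with a seeded
Latin-hypercube multi-start (10 starts by default) and L-BFGS-B.  This is
a deliberately deterministic replacement for posterior sampling: with flat
priors the ML optimum is the MAP, and reruns are bit-reproducible.
Sessions need ≥ 20 trials.  Value traces are *pre-outcome*: `trace[t]` is
the value the trial-t choice and bet were conditioned on — the convention
the regressions require.  Predictive accuracy counts trials whose
higher-valued option matches the actual choice (exact ties count ½).
Fitting is per subject, with no hierarchical pooling, matching the
per-individual accuracy reporting the analyses assume.

## Regressions

All continuous predictors (chosen value, unchosen value, previous bet, win
indicator) are z-scored within subject (population sd); stay (±1) and the
patient indicator (0/1) are not.  Interactions are products of the scaled
columns.  Every model has a single random intercept per subject — no
random slopes — and is estimated by maximum likelihood rather than REML so
that BICs are comparable across fixed-effect structures
(`BIC = −2·llf + (k_fixed + 2)·log n`, counting the two variance
parameters).  Fixed-effect t statistics use residual degrees of freedom
(rows − fixed effects) — a convention, not a per-subject derivation — and
exact row counts are logged per model because listwise deletion (missing
previous bets on block-initial trials; missing pre-onset surprise) differs
across specifications.  BIC differences are only computed between fits on
identical rows (`common_rows` restricts the table first; mismatched rows
are an error).  Bets are treated as a 1–5 ordinal-as-linear response (the
stakes are roughly log-spaced, so the level is approximately the
log-stake); no cumulative-link models are fitted.

Degenerate fits are reported, not hidden: a random-intercept variance at
the boundary sets `singular=True`, and if the residual variance collapses
(noiseless synthetic data) the fixed effects are obtained from the
profiled limit — OLS with subject fixed intercepts (pooled OLS for
between-subject formulas).

## Case statistics

The per-subject win-stay interaction term is the standard 2×2 double
difference of cell mean bets, halved to express it per cell contrast.  The
cohort-level 2×2 ANOVA is a two-way repeated-measures ANOVA (each effect
tested against its own subject × effect error stratum, df (1, n−1)), which
makes it exactly invariant to per-subject bet offsets and exactly
calibrated under normality; its degrees of freedom therefore differ from a
pooled cells-as-observations ANOVA.  Because prior wins raise the stayed-on
option's learned value, a *genuine* win-stay interaction in cell-mean bets
is induced whenever bets track value; error-calibration checks therefore
use an additive-only bet policy (intercept + noise) as the null.

Single-case inference defaults to the plain Z test
(`Z = (x − mean)/sd`, two-tailed normal p), which is what the published
single-case values match; the Crawford–Howell t (sd inflated by
√((n+1)/n), t with n−1 df) is available behind a method flag.  Published
single-case Z values were printed from unrounded inputs, so agreement is
asserted to ±0.05 only.

The percentile sliding-window curve averages the response within a
25-percentile-wide window of each subject's own predictor distribution,
stepped in 1% quantile increments; the curve's x-coordinate is the mean of
per-subject bin centres, and the spread is the between-subject standard
error.  Subjects with fewer than 25 distinct percentile positions are
dropped and logged.

## Numerical conventions and degenerate inputs

- z-scores use population (ddof = 0) sd; zero-variance predictors are set
  to 0 and flagged rather than producing NaNs.
- ANOVA effects with zero numerator sum of squares report F = 0, p = 1.
- Schedule import from CSV cannot recover pre-truncation interval draws;
  `designed_intervals` is `None` for imported schedules.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; cohort subject i uses spawned child i, so
  cohorts are reproducible and extendable.

## Problem sizes used in the checks

Coefficient-recovery checks use 40 subjects × 160 trials (the scale at
which the published fixed effects were estimated); learning-parameter
recovery uses 2,000 concatenated trials; the oracle win-rate check uses
100,000 simulated trials; ANOVA calibration uses 200 replicate cohorts of
40 subjects; model-selection and group-contrast checks use 20 replicate
cohorts.
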