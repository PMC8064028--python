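# betbias

Simulation and analysis toolkit for a **probabilistic reversal betting
task**: a two-armed bandit in which participants first choose one of two
options, then place a post-decision wager (an ordinal bet, 1–5, mapping to
stakes of £1/£2/£5/£10/£20), and finally rate their surprise at the
outcome.  The two options pay off independently with probability 0.3 or
0.7, and these probabilities reverse every 8 or 16 trials.  Because the
options vary *orthogonally*, a rational bettor should scale the wager with
the learned value of the **chosen** option only — which makes the task a
sensitive probe of decision *biases*: the pull of the previous trial's bet,
of the **unchosen** option's value, and of win-stay/lose-switch habits.

The package is aimed at computational-cognitive-neuroscience researchers
who want to develop, power and validate the full analysis chain for such
tasks without any participant data: every stage runs against a synthetic
cohort generator whose group phenotypes (healthy controls, unilateral
medial-prefrontal lesions, a bilateral-vmPFC "strategic bettor") carry the
statistical structure the analyses assume.

## What it implements

**Task engine** (`betbias.task`) — balanced reversal schedules: inter-
reversal intervals drawn from {8, 16} in equal numbers (mean exactly 12),
and the four joint probability combinations each occupying exactly a
quarter of the first 128 trials.

**Synthetic cohorts** (`betbias.cohort`) — agents that learn with the
Rescorla–Wagner delta rule and choose by softmax,

$$Q^c_{t+1} = Q^c_t + \alpha\,(R_t - Q^c_t), \qquad
P(\text{choice}) = \sigma\!\big(\beta\,(Q^c_t - Q^u_t)\big),$$

with the unchosen value $Q^u$ frozen.  Bets follow a linear policy over
within-session z-scaled signals
($b_t = b_0 + w_c z(Q^c_t) + w_u z(Q^u_t) + w_p z(b_{t-1})
+ w_{ws}\,\text{prevwin}\times\text{stay} + \varepsilon$), surprise
ratings track the win/loss outcome and the reward × value product (a proxy
for absolute prediction error).

**Model fitting** (`betbias.rwmodel`) — per-subject maximum-likelihood
estimation of $(\alpha, \beta)$ by seeded multi-start L-BFGS on
transformed parameters, with reconstructed pre-outcome value traces
$Q^c_t, Q^u_t$ for the regressions.

**Bias regressions** (`betbias.regression`) — linear mixed models with a
random intercept per subject and within-subject z-scored predictors, e.g.

    bet_t ~ 1 + Qc_t + bet_{t-1} + (1|subject)

plus unchosen-value, win-stay and patient-interaction variants (M1–M5,
M5u) and the surprise models `surprise ~ R * Qc` (S1/S2), compared by ML
BIC.

**Case statistics** (`betbias.summaries`) — win-stay/lose-switch
proportions (arcsine-transformed), the 2×2 previous-win × stay bet ANOVA
and per-subject interaction term, single-case Z tests (patient vs control
mean/sd; Crawford–Howell t available), winnings binned by bet level, and
percentile sliding-window curves.

**Pipeline + CLI** (`betbias.pipeline`, `betbias` command) — simulate →
fit → analyze → report, all plain CSV, fully seeded and idempotent.

## Worked example

```bash
betbias run --config examples/demo_config.yaml --out out/demo --seed 2
```

simulates 6 controls, 4 unilateral-phenotype and 1 bilateral-phenotype
subjects, fits the learning model to each, and prints (abridged):

```
            total_winnings        mean_bet        win_rate
                      mean median     mean median     mean median
bilateral            299.0  299.0    3.762  3.762    0.544  0.544
control               86.0   72.5    2.858  2.953    0.516  0.514
unilateral            40.5   22.5    2.971  3.015    0.533  0.534

== M1: bet ~ q_chosen + (1|subject)
   q_chosen    +0.3625 (se 0.0217)  t(1581) = +16.69, p = 1.07e-57

== M2: bet ~ q_chosen + prev_bet + (1|subject)
   q_chosen    +0.3215 (se 0.0218)  t(1549) = +14.74, p = 4.05e-46
   prev_bet    +0.2108 (se 0.0219)  t(1549) = +9.64,  p = 2.14e-21

== M5: bet ~ (q_chosen + prev_bet) * patient + (1|subject)
   q_chosen:patient   +0.1019 (se 0.0443)  t(1546) = +2.30, p = 0.0216
   prev_bet:patient   -0.1220 (se 0.0444)  t(1546) = -2.75, p = 0.0061
```

Reading the output: bets rise by ≈0.36 bet levels per z-unit of the chosen
option's learned value (M1); over and above that, bets are dragged toward
the previous trial's bet (M2's `prev_bet` term — the healthy bias); and in
the patient-interaction model the lesion phenotypes show *more* value
sensitivity and *less* previous-bet bias than controls — the strategic,
less-biased pattern the generator encodes.  The bilateral agent, which
couples bets tightly to value, earns the most despite winning barely more
often (win rates all ≈0.5): the money comes from betting high exactly when
a win is likely.

Individual stages are available as `betbias simulate / fit / analyze /
report / validate`, and everything in the CLI is a thin wrapper over the
library functions shown above.

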