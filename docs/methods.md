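# Methods

## The problem and the index

Team-sport practitioners monitor external load with GPS/accelerometer
units and need a non-invasive, session-level marker of neuromuscular
readiness. The package implements a residual-based marker, the
**Locomotor Efficiency Index (LEI)**: a regression model predicts a
session's accelerometer load (PlayerLoad, PL) from seven locomotor
features — total distance, distance above 7.2 km/h, counts of
accelerations > 2.5 m/s² and decelerations < −2.5 m/s², maximal speed,
maximal acceleration and maximal deceleration — and the residual

    ΔPL = PL_predicted − PL_actual

is z-scored *within each player* over the whole monitoring window:

    LEI = (ΔPL − mean_player(ΔPL)) / sd_player(ΔPL)

A positive LEI means the player produced their locomotor output at a
lower body load than expected (efficient, recovered); a negative LEI
means the session cost more than expected (fatigued). Double-session
days are collapsed to the mean of the day's session LEIs.

Downstream, weekly readiness is the mean of the week's daily LEIs,
binned at −0.5/+0.5 into *bad / normal / good*. Week-to-week load
fluctuation is the percentage change of a weekly load sum (total
distance, distance > 25.2 km/h, mechanical load = accelerations >
3.5 m/s² + decelerations < −3.5 m/s²) binned at ±10% and ±30% into
five categories. The signed difference of consecutive weekly LEIs is
the outcome of a linear mixed model with a per-player random
intercept, fitted separately per readiness subset and load metric,
with "no variation" as the reference category. The question the
contrasts answer: given this week's readiness, does loading or
unloading next week move readiness more than holding the load
constant?

## Prediction protocol

Predictions are **out-of-fold** by default (K = 5, fold assignment
seeded): each session is predicted by a model that never saw it. An
ensemble regressor refit in-sample can nearly memorize PL, collapsing
ΔPL toward zero and destroying the index; out-of-fold residuals keep
the index honest. The regressor is pluggable: the default is a
200-tree random forest (`"rf"`); `"linear"` (ordinary least squares)
exists for oracle checks and for settings where the generative map is
known to be linear.

Per-player standardization uses the sample (n−1) SD over the entire
supplied window. Players with fewer than 20 scored sessions, or whose
residual spread is below 1e−8 (an essentially perfect model leaves
nothing to standardize), are excluded with a logged reason rather than
divided by ~0.

## The squad simulator

Real athlete-monitoring data are club-private, so validation uses a
simulator whose ground truth is known. Each player carries a latent
fatigue state updated daily by an impulse-response (Banister-type)
recurrence:

    F(t) = F(t−1)·exp(−1/τ_f) + k_f · impulse(t)

with `impulse` the day's total distance divided by the player's
habitual session volume. Measured PL is a per-player linear
combination of the session features, inflated multiplicatively by
pre-session fatigue and perturbed by Gaussian noise:

    PL = c_p · Σ_j β_j x_j · (1 + γ·F_pre) + ε,  ε ~ N(0, σ²)

Key defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| `n_players`, `n_weeks` | 100, 80 | a squad followed over two ~40-week seasons |
| `sessions_per_week` | 6 | five training days plus a Saturday match, Sunday off |
| `tau_f` | 3 d | acute neuromuscular fatigue largely resolves within ~72 h of a match; with a much longer constant a week's mean fatigue is dominated by carry-over and the weekly LEI decouples from its own week's load |
| `k_f` | 0.15 | steady-state fatigue ≈ 0.5 under nominal loading |
| `gamma` | 0.3 | PL inflated ~15% at steady-state fatigue, within the plausible range of load-cost elevation |
| `noise_sd` | 10 AU | a few percent of a typical ~330 AU session |
| `unload_prob`, `overload_prob` | 0.15 each | programmed taper / overload weeks frequent enough to populate the "large" fluctuation bins |
| `two_session_prob` | 0.1 | occasional double days exercise the daily-averaging rule |
| `match_multiplier` | 1.3 | the match is the weekly load peak |
| `attend_prob` | 0.95 | rotation/absence, exercising the participation filter |
| `player_effect_sd` | 0.05 | individual mechanical-efficiency scatter |

Programmed weeks manipulate **training frequency**, as real tapers do
(fewer and slightly shorter sessions, intensity maintained): a taper
drops two training days and scales the remainder by 0.9 (weekly volume
≈ −36%); an overload adds a second session on three days at 0.8
relative volume (≈ +38%). Manipulating frequency rather than session
volume matters for validity: a volume-scaled taper is visible to the
per-session prediction model, which then absorbs the fatigue
difference into its predictions and removes the very residual signal
the index is supposed to carry. Frequency manipulation leaves
individual sessions looking ordinary, as in real schedules.

PL uses the fatigue carried *into* the day (decayed, before the day's
impulse), so a session's own features never leak the same-day impulse
into the generative fatigue term. The emitted ground-truth series is
end-of-day.

### What the simulator does and does not emulate

It reproduces the longitudinal structure that the analysis depends on:
per-player repeated sessions, weekly blocks with a match peak,
programmed load manipulation, a latent slow state coupling accumulated
load to measured PL, attendance gaps, individual baselines. It does
**not** emulate positional roles, congested multi-match weeks, injury
or illness spells, seasonality of intensity, sensor artifacts, or any
nonlinearity of the true feature→PL map. Passing recovery tests
therefore shows the *pipeline* is sound under a fitness–fatigue
ground truth of this shape — not that real squads satisfy that model.

## Statistical model

The mixed model is linear (normal outcome, identity link), estimated
by restricted maximum likelihood via `statsmodels.MixedLM`, with Wald
95% intervals and p-values and no small-sample (Kenward–Roger-style)
degrees-of-freedom correction. "Standardized β" z-scores the outcome
within the fitted subset and leaves the 0/1 category indicators
untouched; full predictor standardization is available by flag. No
multiple-testing adjustment is applied by default (α = 0.05),
matching common practice for this design; a flag can add it
downstream. Fits require ≥ 2 players, ≥ 10 transitions and ≥ 2
occupied categories including the reference; singular/boundary fits
are flagged, not discarded. The L-BFGS optimizer occasionally walks
into a numerically singular region on boundary fits; the
implementation falls back to BFGS, then to gradient-free Powell and
Nelder–Mead before giving up.

## Numerical and procedural choices

- **Weeks** are non-overlapping 7-day blocks anchored on a
  configurable weekday (Monday); transitions require disjoint windows.
  Weeks with fewer than 3 sessions are dropped from transitions.
- **Boundaries**: readiness `normal` is the closed interval
  [−0.5, 0.5]; the no-variation bin is closed at ±10; −30 and +30
  belong to the moderate bins. Participation of exactly 60% is
  retained (strictly below excluded).
- **Zero base-week load** makes the percentage change undefined; the
  metric's change is set missing and counted in the run log rather
  than guessed.
- **Readiness conditioning** uses the *earlier* week's state by
  default (the prescription question conditions on current
  readiness); conditioning on the later week is a config option.
- **Determinism**: one RNG stream per simulation seeded from
  `SimConfig.seed`; fold shuffling and the forest share the pipeline
  seed; identical inputs give byte-identical CSVs.

## Validation harnesses and problem sizes

The replicate harnesses run the full pipeline on 40-player × 30-week
squads, a size at which every scenario cell is occupied while a
20-replicate run remains a desk-scale computation. Null calibration
switches the fatigue coupling off (γ = 0) and uses the linear
regressor — under the null the generative map is exactly linear, so
the check isolates the calibration of the mixed-model inference — and
requires the share of significant contrasts to sit near the nominal
0.05. Sign recovery uses the full default random-forest pipeline and
requires the qualitative prescription pattern: a large load decrease
after a bad-readiness week raises next week's LEI (positive,
significant), a large increase from normal readiness lowers it
(negative sign).

## Known limitations

- The true feature→PL map is linear by construction, which flatters
  any regressor; the random-forest default is kept because real PL is
  not linear in the features.
- Wald inference with a random intercept only; random slopes and
  within-player autocorrelation beyond the latent fatigue state are
  not modelled.
- Readiness conditioning induces selection (regression to the mean)
  that attenuates contrasts; the harness thresholds test sign
  patterns, not effect magnitudes, for exactly this reason.
- The participation filter uses the observed union of training dates
  as the team schedule when none is supplied, which under-counts
  sessions no retained player attended.
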