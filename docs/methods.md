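# Methods

## Task model

The simulator reproduces the self-paced home-cage 5-CSRTT as a
deterministic state machine driven by a behavioral agent and a seeded
random generator. Time is continuous (float seconds since experiment
start; no tick quantization, since latency distributions are continuous);
the experiment clock starts at dark onset (lights off at 12:00 by default,
12-h dark phase).

A trial in an SD-controlled stage: initiation poke → 5-s ITI → one of five
holes lit for the stage's SD → response window of SD + 2-s limited hold.
A poke during the ITI ends the trial as *premature*; a poke in the lit
hole is *correct* (pellet, then a 5-s eat-interval after collection); a
poke in another hole is *incorrect*; no poke in the window is an
*omission*. Incorrect, premature and omitted trials trigger a 5-s time-out
with the houselight on (home-cage presets) or off (conventional-training
preset); in the single-cue shaping stage incorrect pokes are not punished.
The four outcomes are mutually exclusive and exhaustive, so
`#correct + #incorrect + #omission + #premature = #trials` holds for every
closed log — this conservation is enforced by tests.

Decisions with a defensible alternative:

* **Cue selection** is i.i.d. uniform over the five holes
  ("pseudo-random"); an optional no-immediate-repeat flag excludes the
  previous hole.
* **Only the first ITI poke** counts as the trial's premature response;
  further pokes during the time-out are not additional prematures, because
  %premature is defined per trial.
* **Incorrect pokes during the limited hold** count as incorrect, same as
  during the SD — only in-window vs. out-of-window matters.
* **Omission time-outs** switch the houselight on like the other error
  time-outs (flag-controlled).
* A trial in progress when the access window closes **runs to
  completion** (flagged in the log); no new trial starts outside the
  window, under any agent and seed (property-tested).
* A scripted or sampled response slower than the response window is
  reclassified as an omission rather than rejected.

## Stage ladder and advancement

Stages: magazine training (50 pellet deliveries at a variable ITI drawn
uniformly from {4, 8, 16, 32} s; collection triggers the next trial, so no
eat-interval applies there), five-lit-holes (50 trials, no ITI — lights on
until poke), single-cue untimed, six SD stages, and a final baseline block
at SD 1. The SD titration "16 s down to 1 s in five steps" leaves the
intermediate values open; the default ladder is **16, 8, 4, 2, 1.5, 1 s**
(halving steps, conventional in 5-CSRTT shaping, with a 1.5-s step to make
five reductions), user-overridable in the protocol YAML.

The advancement criterion is evaluated online after every closed trial:
≥ 50 started trials in the stage, and over the last 20 trials accuracy
> 80% with either window omissions < 20% or > 200 stage-correct trials.
All comparisons are strict; a window of exactly 80% accuracy does not
pass. The same criterion governs the untimed single-cue stage (omissions
are impossible there, so it reduces to the started-trial minimum plus
window accuracy) and is applied a second time within SD 1 as the "stable
baseline" endpoint, since no other endpoint rule is defined. The
implementation is checked trial-by-trial against a brute-force
re-computation on randomized histories.

## Behavioral agent

No per-trial behavioral model exists for this task in the literature the
package draws on; the agent is this package's own generative stand-in,
and its defaults are tuning choices, not measured animal values. Per
trial it samples:

| parameter | default | meaning |
| --- | --- | --- |
| `p_correct` | 0.87 | choice accuracy given a response |
| `p_omit_base` | 0.15 | omission probability at the 1-s reference SD |
| `omit_sd_slope` | 0.25 | omission increase as SD shrinks: `p_omit(sd) = clamp(p_omit_base + slope·(1 − sd/1 s), 0, 1)` |
| `premature_hazard` | 0.001 /s | Poisson poke rate during the ITI; premature iff the first event lands inside the ITI |
| `init_rate_dark`, `init_rate_light` | 0.1, 0.01 /s | trial-initiation rates by phase; waiting times are exact piecewise exponentials across phase boundaries |
| latency medians (σ) | 1.2 s (0.35), 1.8 s (0.4) | log-normal correct-response and magazine latencies (positive support, right skew) |
| `satiety_gain` | 0 | omission increment per 100 pellets earned that day |

The defaults were chosen once to make a trained agent's time-restricted
baseline resemble a competent rat — ~85–90% accuracy, ~15% omissions,
prematures below 1% at a 5-s ITI, and ~390 started trials per 2.5-h
window — and are loadable per subject from YAML. Choice errors are uniform
over the four unlit holes (no spatial error structure is modeled). The
omission/SD slope reproduces the qualitative pattern that shorter stimuli
are missed more often.

**Drug kernel.** Pharmacological effects are phenomenological: a peak
effect at injection decaying as `2^(−(t − onset)/half_life)` (default
half-life 30 min, injection 20 min before dark onset), additive on
probabilities and hazards, multiplicative on latencies and initiation
rate (factor interpolated toward 1 as the effect decays). No
pharmacokinetics beyond this kernel are modeled. Crossover studies use a
cyclic Latin square: each subject receives each dose once, positions
balanced whenever the subject count is a multiple of the dose count.

## What the simulation does and does not show

The generator emulates the *structure* of the task — stage progression,
access windows, circadian initiation bias, outcome frequencies, latency
scales, dose- and time-dependent drug modulation — so passing tests
demonstrate that the controller logic, criterion algebra, log format,
metrics and statistics behave correctly on data of realistic shape and
size. The agent has no learning dynamics (acquisition arises from the
staged criteria, not plasticity), no spatial biases, no post-error
slowing, and no pellet-motivation feedback beyond the optional satiety
term; empirical animal values (training times, group differences,
drug effect sizes) are properties of animals, not of this package, and
are never asserted by its tests.

## Metrics and statistics

Accuracy is `100·#correct/(#correct + #incorrect)`; a source document for
this task family prints the formula with the factor of 100 in the
denominator, which evaluates to ~0.01 for ~85% performance — this package
treats that as a typographical slip and uses the conventional form, which
matches the ~85% values such tables report. %omissions and %prematures
are per total trials. Trials with magazine latency > 10 s (strictly; a
latency of exactly 10 s is retained) are excluded — by default the whole
trial is removed from the analysis at hand ("whole-trial" scope), with a
"latency-only" scope that drops them solely from the magazine-latency
mean, because the defining sentence is ambiguous between the two.
Partitions use half-open intervals with boundary trials assigned to the
later block; a 2.5-h session in 30-min blocks yields exactly five.

Group comparisons apply a Shapiro–Wilk gate at α = 0.05 (the α is this
package's choice): both samples normal → t test, else Wilcoxon rank-sum /
signed-rank; the fired branch is recorded. The mixed / repeated-measures
ANOVA delegates to pingouin (analysis plumbing, not this package's
contribution) behind a strict balanced-design guard — missing
within-subject cells raise rather than impute. Supported designs: one
between + one within factor, or one/two within factors (the dose × time
design); Greenhouse–Geisser correction is exposed but off by default.
Reported degrees of freedom are the standard ones
(levels − 1, (levels − 1)(subjects − 1)); published reports of such
designs sometimes bracket df inconsistently, and no attempt is made to
match any particular printed bracketing. Benjamini–Hochberg adjustment is
the step-up procedure implemented directly (sort ascending, running
minimum of `m·p_j/j` from the largest rank, clip at 1) and cross-checked
against statsmodels on random vectors.

## Numerical and reproducibility choices

* Identical (config, agent parameters, seed) produce byte-identical logs;
  the CLI derives per-subject seeds as `SeedSequence([master, index])`, so
  adding subjects never changes existing streams.
* Timestamps are monotone by construction and validated on read; the
  JSONL log is the single source of truth (CSV is a lossless export).
* Problem sizes used by the shipped checks — 100 stochastic training runs,
  1,000 random criterion histories and p-vectors, 500 random trial
  tables, ~400-trial sessions for parameter recovery, 120-replicate ANOVA
  null calibration — were chosen to keep Monte-Carlo error small (binomial
  SE tolerances are computed in the tests) while the whole suite runs in
  well under a minute per module.

## Known limitations

Hardware control, real-time operation and proprietary rig file formats
are out of scope. The conventional-training preset carries only the
constants that distinguish it (no eat-interval, houselight off during
time-outs, 30-min daily sessions); its per-session criterion bookkeeping
beyond the shared machinery is not modeled. The drug kernel is
phenomenological and the agent's parameters are not fitted to any
dataset — parameter *recovery* (simulate → analyze → recover the
generative rates) is tested, parameter *estimation* from real logs is
left to the user's statistical workflow.
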