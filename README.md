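# sp5c — self-paced home-cage 5-CSRTT simulator and analysis pipeline

The 5-choice serial reaction time task (5-CSRTT) is the standard rodent
assay of visuospatial attention and motor impulsivity: the animal waits
through an inter-trial interval (ITI), attends five apertures for a brief
light cue of stimulus duration SD, and nose-pokes the lit hole for a food
pellet. In the **self-paced** home-cage variant (SP-5-CSRTT) the animal
lives in a cage connected to the operant box and initiates trials itself,
around the clock (unlimited access, *UA*) or only during the first 2.5 h of
the dark phase (time-restricted, *TR*); an adaptive program advances it
through a ladder of training stages automatically.

`sp5c` is a discrete-event re-implementation of that task controller plus
the complete behavioral-metrics and statistics pipeline, with a stochastic
rat model in place of the animal. It is written for behavioral
neuroscientists and tool builders who want to prototype protocol variants,
challenge and pharmacology session designs, and analysis choices entirely
at the desk — before any animal is run.

## What is implemented

* **Protocol** (`sp5c.protocol`): validated task configurations; shipped
  presets UA, TR (differing solely in trial availability) and CT
  (conventional daily 30-min sessions). Stage ladder: magazine training
  (50 pellets at variable 4/8/16/32-s ITI), five-lit-holes (50 trials),
  single-cue untimed, then SDs titrated 16 → 8 → 4 → 2 → 1.5 → 1 s, and a
  final baseline block at SD 1.
* **Advancement criterion**: a stage with SD control is passed once the
  animal has ≥ 50 started trials in the stage and, over a 20-trial sliding
  window evaluated online after every trial, accuracy > 80% together with
  either window omissions < 20% or > 200 correct trials in the stage.
* **Engine** (`sp5c.engine`): the trial state machine — 5-s ITI, response
  window SD + 2-s limited hold, 5-s time-outs with houselight for
  incorrect, premature and omitted trials, reward collection followed by a
  5-s eat-interval, pseudo-random cue positions, access-window enforcement,
  timestamped event logs. Pure given (config, agent, seed).
* **Agent** (`sp5c.agent`): stochastic responder with choice accuracy,
  SD-dependent omissions, a premature-poke hazard during the ITI,
  log-normal latencies, circadian initiation rates, and a half-life decay
  kernel for drug effects; scripted deterministic responders; Latin-square
  crossover dosing schedules.
* **Metrics** (`sp5c.metrics`): accuracy = 100·#correct/(#correct +
  #incorrect); %omissions and %prematures of all trials; correct-response
  and magazine latencies with the > 10-s magazine-latency exclusion;
  dark/light, 30-min-block and first-N/first-hours partitions.
* **Stats** (`sp5c.stats`): Shapiro–Wilk-gated t/Wilcoxon comparisons,
  mixed and two-way repeated-measures ANOVA, Benjamini–Hochberg FDR.
* **I/O and CLI** (`sp5c.eventlog_io`, `sp5c.cli`): JSONL/CSV event logs,
  trial-table reconstruction, and the `sp5c` command with `train`,
  `challenge`, `drugstudy`, `analyze` and `export` subcommands.

## Worked example

Train a simulated rat on the time-restricted protocol, then measure a
baseline day at SD 1:

```python
from sp5c import build_preset, StochasticAgent, run_session, \
    events_to_trials, summarize
from sp5c.experiments import run_training, training_summary

tr = build_preset("TR")
log = run_training(tr, StochasticAgent(), seed=42, subject_id="rat01")
s = training_summary(log)
print(f"days to criterion: {s.days_to_criterion:.2f}")
print(f"trials to criterion: {s.trials_to_criterion}")

baseline = run_session(tr, StochasticAgent(), seed=43, subject_id="rat01",
                       initial_stage=len(tr.stages) - 1, freeze_stage=True,
                       horizon_s=86_400.0)
print(summarize(events_to_trials(baseline)))
```

prints

```
days to criterion: 1.03
trials to criterion: 500
SessionMetrics(n_started=386, accuracy_pct=88.37920489296636,
               omission_pct=15.284974093264248, premature_pct=0.0,
               correct_latency_mean=1.2365876509016986,
               magazine_latency_mean=1.9023616060244677,
               n_latency_excluded=0)
```

This agent needed the minimum 50 trials in each of the 10 stages (500
total) and finished the ladder during its second 2.5-h access window (1.03
days). Its baseline day shows 386 started trials with ~88% accuracy, ~15%
omissions and no prematures — the profile of a well-trained rat on the
time-restricted schedule. The same pipeline from the shell:

```bash
sp5c train --variant TR --n-subjects 12 --seed 7 --out-dir runs/tr
sp5c challenge --kind var_iti --variant TR --n-subjects 12 --seed 8 \
     --out-dir runs/chal
sp5c drugstudy --doses 0,0.1,0.3 --n-subjects 10 --seed 9 --out-dir runs/drug
sp5c analyze runs/tr/S00.events.jsonl --partitions session,phase,blocks \
     --out-dir runs/report
```

Every output directory contains a `manifest.json` with the per-subject
seeds needed to reproduce it bit-exactly.

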