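"""Stochastic and scripted response models standing in for the animal.

The engine asks an agent, for each trial, when it initiates, whether it
pokes prematurely during the ITI, whether it responds to the cue, which
hole it chooses, and its response and magazine latencies. The stochastic
model composes:

* a choice accuracy ``p_correct`` (given a response);
* an omission probability rising as the stimulus duration shrinks:
  ``p_omit(sd) = clamp(p_omit_base + omit_sd_slope * (1 - sd/sd_ref), 0, 1)``
  with ``sd_ref = 1 s``, plus an optional satiety increment per 100 pellets
  earned that day;
* a constant premature-poke hazard (events/s) during the ITI — the trial
  ends prematurely iff the first hazard event falls inside the ITI;
* log-normal correct-response and magazine latencies;
* circadian modulation of trial initiation: exponential waiting times with
  separate dark- and light-phase rates (piecewise sampling, exact for a
  piecewise-constant-rate Poisson process);
* optional drug effects with a phenomenological exponential-decay kernel
  (half-life parameterization): additive on probabilities and hazards,
  multiplicative on latencies and initiation rate.

No learning dynamics are modeled: acquisition arises from the staged
advancement criteria, not from plasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

from .protocol import LightCycle, StageSpec, UNBOUNDED

__all__ = [
    "AgentParams",
    "DrugEffect",
    "AgentAction",
    "StochasticAgent",
    "ScriptedAgent",
    "scripted_agent",
    "decide",
    "drug_magnitude",
    "effective_params",
    "latin_square_schedule",
    "load_agent_params",
    "save_agent_params",
]

SD_REF = 1.0  # seconds; reference SD for the omission/SD relation


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of the stochastic rat model.

    Defaults are tuned to produce time-restricted baseline behavior in the
    ballpark of a well-trained rat: ~85% accuracy, ~15-20% omissions at a
    1-s stimulus, sub-1% prematures at a 5-s ITI, and a few hundred trial
    initiations per 2.5-h dark-phase window.
    """

    p_correct: float = 0.87
    p_omit_base: float = 0.15
    omit_sd_slope: float = 0.25
    premature_hazard: float = 0.001  # pokes/s during the ITI
    init_rate_dark: float = 0.1  # initiations/s when trials are available
    init_rate_light: float = 0.01
    correct_latency_median: float = 1.2  # s
    correct_latency_sigma: float = 0.35  # log-scale SD
    magazine_latency_median: float = 1.8  # s
    magazine_latency_sigma: float = 0.4
    satiety_gain: float = 0.0  # omission-probability increment / 100 pellets


@dataclass(frozen=True)
class DrugEffect:
    """Time-decaying phenomenological drug modulation.

    The realized effect at time ``t`` is the peak effect scaled by
    ``2 ** (-(t - onset_t) / half_life)`` for ``t >= onset_t`` and zero
    before onset. ``delta_*`` fields are signed peak effects; ``*_scale``
    fields are multiplicative factors at peak (1.0 = no effect), linearly
    interpolated toward 1 as the effect decays.
    """

    dose: float = 0.0  # mg/kg, label only
    onset_t: float = 0.0  # seconds on the experiment clock
    half_life: float = 1800.0  # seconds
    delta_p_correct: float = 0.0
    delta_p_omit: float = 0.0
    delta_premature_hazard: float = 0.0
    delta_latency_scale: float = 1.0
    delta_init_rate_scale: float = 1.0

    def scaled(self, factor: float) -> "DrugEffect":
        """Linearly scale all peak effects (e.g., by dose / reference dose)."""
        return replace(
            self,
            delta_p_correct=self.delta_p_correct * factor,
            delta_p_omit=self.delta_p_omit * factor,
            delta_premature_hazard=self.delta_premature_hazard * factor,
            delta_latency_scale=1.0 + (self.delta_latency_scale - 1.0) * factor,
            delta_init_rate_scale=1.0 + (self.delta_init_rate_scale - 1.0) * factor,
        )


@dataclass(frozen=True)
class AgentAction:
    """One trial's worth of behavior, sampled before the trial runs."""

    initiate_delay: float = 0.0
    premature_time: Optional[float] = None  # seconds into the ITI, or None
    responds: bool = True
    chosen_hole: Optional[int] = None  # 1-5; None when not responding
    response_latency: Optional[float] = None  # from stimulus onset
    magazine_latency: Optional[float] = None


def drug_magnitude(effect: DrugEffect, t: float) -> float:
    """Decay-kernel weight in [0, 1]: 0 before onset, 1 at onset, halving
    every ``half_life`` seconds after."""
    if t < effect.onset_t:
        return 0.0
    return 2.0 ** (-(t - effect.onset_t) / effect.half_life)


def effective_params(
    params: AgentParams,
    effects: Sequence[DrugEffect],
    t: float,
    *,
    pellets_today: int = 0,
) -> AgentParams:
    """Apply drug kernels and satiety to the base parameters at time ``t``."""
    p_corr = params.p_correct
    p_omit = params.p_omit_base + params.satiety_gain * (pellets_today / 100.0)
    hazard = params.premature_hazard
    lat_scale = 1.0
    init_scale = 1.0
    for eff in effects:
        m = drug_magnitude(eff, t)
        if m == 0.0:
            continue
        p_corr += eff.delta_p_correct * m
        p_omit += eff.delta_p_omit * m
        hazard += eff.delta_premature_hazard * m
        lat_scale *= 1.0 + (eff.delta_latency_scale - 1.0) * m
        init_scale *= 1.0 + (eff.delta_init_rate_scale - 1.0) * m
    return replace(
        params,
        p_correct=min(max(p_corr, 0.0), 1.0),
        p_omit_base=min(max(p_omit, 0.0), 1.0),
        premature_hazard=max(hazard, 0.0),
        init_rate_dark=params.init_rate_dark * init_scale,
        init_rate_light=params.init_rate_light * init_scale,
        correct_latency_median=params.correct_latency_median * lat_scale,
        magazine_latency_median=params.magazine_latency_median * lat_scale,
    )


def p_omit_at_sd(params: AgentParams, sd: Optional[float]) -> float:
    """Omission probability at a given stimulus duration (0 when the light
    stays on until a response)."""
    if sd is None or math.isinf(sd):
        return 0.0
    p = params.p_omit_base + params.omit_sd_slope * (1.0 - sd / SD_REF)
    return min(max(p, 0.0), 1.0)


def _sample_initiate_delay(
    params: AgentParams,
    t: float,
    start_clock: float,
    clock: LightCycle,
    rng: np.random.Generator,
) -> float:
    """Exponential waiting time with phase-dependent rate.

    Sampled piecewise across dark/light boundaries: within each constant-rate
    segment draw Exp(rate); if the draw overshoots the segment, advance to
    the boundary and redraw (exact inhomogeneous-Poisson first-event time).
    """
    delay = 0.0
    for _ in range(10_000):
        clock_h = (start_clock + (t + delay) / 3600.0) % 24.0
        dark = clock.is_dark(clock_h)
        rate = params.init_rate_dark if dark else params.init_rate_light
        since_off = (clock_h - clock.lights_off_clock) % 24.0
        to_boundary = (
            (clock.dark_duration - since_off) if dark else (24.0 - since_off)
        ) * 3600.0
        if rate <= 0.0:
            delay += to_boundary
            continue
        w = rng.exponential(1.0 / rate)
        if w <= to_boundary:
            return delay + w
        delay += to_boundary
    raise RuntimeError("initiation sampling did not converge (zero rates?)")


def decide(
    params: AgentParams,
    effects: Sequence[DrugEffect],
    stage: StageSpec,
    t: float,
    clock: LightCycle,
    rng: np.random.Generator,
    *,
    start_clock: float = 12.0,
    iti: Optional[float] = None,
    sd: Optional[float] = None,
    pellets_today: int = 0,
) -> AgentAction:
    """Sample one trial's behavior at experiment time ``t`` (seconds).

    ``iti`` and ``sd`` are the realized per-trial values (the engine draws
    them from the stage spec or a challenge design before asking).
    """
    eff = effective_params(params, effects, t, pellets_today=pellets_today)
    delay = _sample_initiate_delay(eff, t, start_clock, clock, rng)

    if stage.kind == "magazine":
        return AgentAction(
            initiate_delay=delay,
            responds=False,
            magazine_latency=_lognormal(
                eff.magazine_latency_median, eff.magazine_latency_sigma, rng
            ),
        )

    sd = stage.sd if sd is None else sd
    premature_time = None
    if iti is not None and eff.premature_hazard > 0.0:
        first = rng.exponential(1.0 / eff.premature_hazard)
        if first < iti:
            premature_time = first

    responds = rng.random() >= p_omit_at_sd(eff, sd)
    chosen = None
    resp_lat = None
    mag_lat = None
    if responds:
        correct = rng.random() < eff.p_correct
        chosen = -1 if correct else -int(2 + rng.integers(4))  # coded choice
        resp_lat = _lognormal(
            eff.correct_latency_median, eff.correct_latency_sigma, rng
        )
        window = None if sd is None or math.isinf(sd) else sd + stage.limited_hold
        if window is not None and resp_lat >= window:
            # Truncate into the response window (keeps responds=True honest).
            resp_lat = window * (0.5 + 0.5 * rng.random())
        mag_lat = _lognormal(
            eff.magazine_latency_median, eff.magazine_latency_sigma, rng
        )
    return AgentAction(
        initiate_delay=delay,
        premature_time=premature_time,
        responds=responds,
        chosen_hole=chosen,
        response_latency=resp_lat,
        magazine_latency=mag_lat,
    )


def _lognormal(median: float, sigma: float, rng: np.random.Generator) -> float:
    return float(rng.lognormal(mean=math.log(median), sigma=sigma))


class StochasticAgent:
    """Adapter giving the engine a single ``decide`` entry point.

    ``chosen_hole`` uses a relative code the engine resolves against the lit
    hole: ``-1`` means "the lit hole", ``-(2+k)`` means "the k-th of the four
    other holes". This keeps the agent ignorant of hole identity, so choice
    accuracy is exactly ``p_correct`` regardless of the cue sequence.
    """

    def __init__(
        self,
        params: Optional[AgentParams] = None,
        effects: Sequence[DrugEffect] = (),
    ):
        self.params = params or AgentParams()
        self.effects = tuple(effects)

    def decide(self, stage, t, clock, rng, **kw) -> AgentAction:
        return decide(self.params, self.effects, stage, t, clock, rng, **kw)


class ScriptedAgent:
    """Deterministic responder for tests and worked examples.

    ``perfect``: immediate initiation, correct response at half the stimulus
    duration (0.5 s when the light stays on), 1-s magazine latency.
    ``always_omit``: initiates but never responds. ``always_premature``:
    pokes 0.1 s into every ITI. ``fixed_sequence``: cycles through a list of
    outcome labels (``correct``/``incorrect``/``omission``/``premature``).
    """

    _OUTCOMES = ("correct", "incorrect", "omission", "premature")

    def __init__(self, script: str, sequence: Optional[Sequence[str]] = None):
        if script == "fixed_sequence":
            if not sequence:
                raise ValueError("fixed_sequence script requires a non-empty list")
            bad = set(sequence) - set(self._OUTCOMES)
            if bad:
                raise ValueError(f"unknown outcome labels in sequence: {bad}")
        elif script not in ("perfect", "always_omit", "always_premature"):
            raise ValueError(f"unknown script: {script!r}")
        self.script = script
        self.sequence = tuple(sequence) if sequence else ()
        self._i = 0

    def _next_label(self) -> str:
        label = self.sequence[self._i % len(self.sequence)]
        self._i += 1
        return label

    def decide(self, stage, t, clock, rng, *, iti=None, sd=None, **kw) -> AgentAction:
        sd = stage.sd if sd is None else sd
        if stage.kind == "magazine":
            return AgentAction(initiate_delay=0.0, responds=False, magazine_latency=1.0)
        half_sd = 0.5 if sd is None or math.isinf(sd) else 0.5 * sd
        if self.script == "perfect":
            label = "correct"
        elif self.script == "always_omit":
            label = "omission"
        elif self.script == "always_premature":
            label = "premature"
        else:
            label = self._next_label()
        if label == "correct":
            return AgentAction(
                initiate_delay=0.0,
                responds=True,
                chosen_hole=-1,
                response_latency=half_sd,
                magazine_latency=1.0,
            )
        if label == "incorrect":
            return AgentAction(
                initiate_delay=0.0,
                responds=True,
                chosen_hole=-2,
                response_latency=half_sd,
                magazine_latency=None,
            )
        if label == "premature":
            poke_at = 0.1 if iti is None else min(0.1, iti / 2.0)
            return AgentAction(initiate_delay=0.0, premature_time=poke_at, responds=False)
        return AgentAction(initiate_delay=0.0, responds=False)


def scripted_agent(script: str, sequence: Optional[Sequence[str]] = None) -> ScriptedAgent:
    return ScriptedAgent(script, sequence)


def latin_square_schedule(
    doses: Sequence[float], n_subjects: int, seed: Optional[int] = None
) -> list:
    """Per-subject dose orders from a balanced (cyclic) Latin square.

    Row ``i`` of the square is ``doses`` rotated by ``i``; rows are assigned
    to subjects in order, cycling when ``n_subjects`` exceeds the number of
    doses, so each dose appears in each position equally often whenever
    ``n_subjects`` is a multiple of ``len(doses)``. ``seed`` shuffles the
    dose labels once before building the square (a random starting order),
    not the balance structure.
    """
    doses = list(doses)
    if len(doses) < 2:
        raise ValueError("need at least 2 doses for a crossover schedule")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seed is not None:
        rng = np.random.default_rng(seed)
        doses = [doses[i] for i in rng.permutation(len(doses))]
    k = len(doses)
    square = [[doses[(i + j) % k] for j in range(k)] for i in range(k)]
    return [list(square[i % k]) for i in range(n_subjects)]


# ---------------------------------------------------------------------------
# Parameter files: one agent per subject ID (YAML mapping)


def save_agent_params(agents: dict, path) -> None:
    """Write ``{subject_id: AgentParams}`` to a YAML file."""
    doc = {
        str(sid): {k: v for k, v in vars(p).items()} for sid, p in agents.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_agent_params(path) -> dict:
    """Read ``{subject_id: AgentParams}`` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return {str(sid): AgentParams(**(fields or {})) for sid, fields in doc.items()}
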