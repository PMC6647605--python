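"""Discrete-event trial state machine for the self-paced 5-CSRTT.

One trial in a stimulus-duration (SD) stage unfolds as:

    trial_start -> iti_start -> [premature_poke -> timeout]        (premature)
                              | stimulus_on -> correct_poke
                                   -> pellet_delivered
                                   -> reward_collected             (correct)
                              | stimulus_on -> incorrect_poke
                                   [-> timeout if punished]        (incorrect)
                              | stimulus_on -> limited_hold_expired
                                   -> omission -> timeout          (omission)

The next trial becomes available ``eat_interval`` seconds after reward
collection (correct trials) or at time-out end (error trials). Timestamps
are continuous seconds since experiment start; no tick quantization.

The engine is pure given (config, agent, seed): identical inputs produce
byte-identical event logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .protocol import (
    AccessWindow,
    ChallengeSpec,
    CriterionSpec,
    LightCycle,
    ProtocolConfig,
    StageSpec,
)

__all__ = [
    "Event",
    "TrialRecord",
    "WindowMetrics",
    "EVENT_KINDS",
    "select_cue_hole",
    "evaluate_criterion",
    "run_trial",
    "run_session",
]

EVENT_KINDS = (
    "session_open",
    "session_close",
    "trial_start",
    "iti_start",
    "premature_poke",
    "stimulus_on",
    "correct_poke",
    "incorrect_poke",
    "limited_hold_expired",
    "omission",
    "timeout_start",
    "timeout_end",
    "pellet_delivered",
    "reward_collected",
    "stage_advanced",
    "criterion_evaluated",
)

OUTCOMES = ("correct", "incorrect", "omission", "premature")

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class Event:
    t: float
    day: int
    kind: str
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    stage_id: int
    t_start: float
    outcome: str
    hole: Optional[int]
    iti_used: Optional[float]
    sd_used: Optional[float]
    correct_latency: Optional[float]
    magazine_latency: Optional[float]
    in_dark_phase: bool
    incomplete: bool = False


@dataclass(frozen=True)
class WindowMetrics:
    n_window: int
    accuracy_pct: Optional[float]
    omission_pct: float
    started_in_stage: int
    correct_in_stage: int


def _day(t: float) -> int:
    return int(t // SECONDS_PER_DAY)


def _ev(t: float, kind: str, **detail) -> Event:
    return Event(t=t, day=_day(t), kind=kind, detail=detail)


def select_cue_hole(
    rng: np.random.Generator,
    recent_holes: Sequence[int] = (),
    *,
    no_immediate_repeat: bool = False,
) -> int:
    """Pseudo-random cue position: i.i.d. uniform over holes 1-5.

    With ``no_immediate_repeat`` the previous trial's hole is excluded
    (uniform over the remaining four).
    """
    if no_immediate_repeat and recent_holes:
        candidates = [h for h in range(1, 6) if h != recent_holes[-1]]
        return int(candidates[rng.integers(len(candidates))])
    return int(rng.integers(1, 6))


def _resolve_hole(coded: Optional[int], lit: int, rng: np.random.Generator) -> int:
    """Map an agent's relative hole code onto a physical hole.

    ``-1`` is the lit hole; ``-(2+k)``, k in 0..3, is the k-th non-lit hole;
    positive values 1-5 are literal positions.
    """
    if coded is None:
        raise ValueError("responding action must carry a chosen hole")
    if coded >= 1:
        return int(coded)
    if coded == -1:
        return lit
    others = [h for h in range(1, 6) if h != lit]
    return others[-coded - 2]


def evaluate_criterion(
    history: Sequence[TrialRecord], spec: CriterionSpec
) -> Tuple[bool, WindowMetrics]:
    """Online stage-advancement check over the stage's trial history.

    Accuracy and %omissions are computed on the last ``window_len`` trials;
    the started-trial minimum and the correct-trial alternative are counted
    over the whole stage. All threshold comparisons are strict.
    """
    n = len(history)
    window = history[max(0, n - spec.window_len):]
    c_w = sum(1 for r in window if r.outcome == "correct")
    i_w = sum(1 for r in window if r.outcome == "incorrect")
    o_w = sum(1 for r in window if r.outcome == "omission")
    accuracy = 100.0 * c_w / (c_w + i_w) if (c_w + i_w) > 0 else None
    omission = 100.0 * o_w / len(window) if window else 0.0
    correct_in_stage = sum(1 for r in history if r.outcome == "correct")
    metrics = WindowMetrics(
        n_window=len(window),
        accuracy_pct=accuracy,
        omission_pct=omission,
        started_in_stage=n,
        correct_in_stage=correct_in_stage,
    )
    passed = (
        n >= spec.min_started
        and accuracy is not None
        and accuracy > spec.accuracy_gt
        and (omission < spec.omission_lt or correct_in_stage > spec.correct_alt_gt)
    )
    return passed, metrics


def run_trial(
    stage: StageSpec,
    action,
    t0: float,
    rng: np.random.Generator,
    *,
    iti: Optional[float] = None,
    sd: Optional[float] = None,
    trial_index: int = 0,
    in_dark: bool = True,
    recent_holes: Sequence[int] = (),
    no_immediate_repeat: bool = False,
) -> Tuple[TrialRecord, List[Event], float]:
    """Run one trial starting at ``t0``; return (record, events, next_avail).

    ``iti``/``sd`` are the realized per-trial values (already drawn by the
    caller from the stage spec or a challenge design). ``next_avail`` is the
    earliest time the next trial may start.
    """
    for name in ("initiate_delay", "premature_time", "response_latency",
                 "magazine_latency"):
        v = getattr(action, name, None)
        if v is not None and v < 0:
            raise ValueError(f"negative {name} in agent action")

    sd = stage.sd if sd is None else sd
    events = [
        _ev(t0, "trial_start", stage_id=stage.stage_id, trial_index=trial_index,
            iti=iti, sd=None if sd is None or math.isinf(sd) else sd)
    ]

    def timeout(t_from: float) -> float:
        events.append(
            _ev(t_from, "timeout_start", houselight=stage.houselight_on_timeout)
        )
        t_end = t_from + stage.timeout
        events.append(_ev(t_end, "timeout_end"))
        return t_end

    def rewarded(t_poke: float) -> float:
        events.append(_ev(t_poke, "pellet_delivered"))
        t_coll = t_poke + action.magazine_latency
        events.append(_ev(t_coll, "reward_collected"))
        return t_coll + stage.eat_interval

    def make_record(outcome, hole=None, correct_latency=None,
                    magazine_latency=None) -> TrialRecord:
        return TrialRecord(
            trial_index=trial_index,
            stage_id=stage.stage_id,
            t_start=t0,
            outcome=outcome,
            hole=hole,
            iti_used=iti,
            sd_used=sd if sd is None or not math.isinf(sd) else None,
            correct_latency=correct_latency,
            magazine_latency=magazine_latency,
            in_dark_phase=in_dark,
        )

    if stage.kind == "magazine":
        # Pellet auto-delivered after the variable ITI; collection starts
        # the next trial.
        events.append(_ev(t0, "iti_start", iti=iti))
        t_pellet = t0 + (iti or 0.0)
        next_avail = rewarded(t_pellet)
        record = make_record("correct", magazine_latency=action.magazine_latency)
        return record, events, next_avail

    unbounded = sd is None or math.isinf(sd)

    if stage.kind == "five_lit":
        # All five holes lit until a poke in any of them; every response is
        # rewarded, so omissions cannot occur.
        events.append(_ev(t0, "stimulus_on", holes=list(range(1, 6))))
        if not action.responds or action.response_latency is None:
            raise ValueError("five_lit stage requires a responding action")
        t_poke = t0 + action.response_latency
        hole = action.chosen_hole if (action.chosen_hole or 0) >= 1 else \
            select_cue_hole(rng)
        events.append(_ev(t_poke, "correct_poke", hole=hole))
        next_avail = rewarded(t_poke)
        record = make_record("correct", hole=hole,
                             correct_latency=action.response_latency,
                             magazine_latency=action.magazine_latency)
        return record, events, next_avail

    # single_cue_untimed and sd_limited share the ITI -> cue -> response path
    events.append(_ev(t0, "iti_start", iti=iti))
    iti = iti or 0.0
    if action.premature_time is not None and action.premature_time < iti:
        t_poke = t0 + action.premature_time
        events.append(_ev(t_poke, "premature_poke"))
        next_avail = timeout(t_poke)
        return make_record("premature"), events, next_avail

    t_stim = t0 + iti
    lit = select_cue_hole(rng, recent_holes, no_immediate_repeat=no_immediate_repeat)
    events.append(
        _ev(t_stim, "stimulus_on", hole=lit,
            sd=None if unbounded else sd)
    )

    window = None if unbounded else sd + stage.limited_hold
    responds = action.responds and action.response_latency is not None
    if responds and window is not None and action.response_latency >= window:
        responds = False  # too slow: counts as an omission
    if not responds:
        if window is None:
            raise ValueError(
                "non-responding action in an untimed stage: the cue would "
                "stay lit forever"
            )
        t_exp = t_stim + window
        events.append(_ev(t_exp, "limited_hold_expired"))
        events.append(_ev(t_exp, "omission"))
        next_avail = timeout(t_exp)
        return make_record("omission"), events, next_avail

    t_poke = t_stim + action.response_latency
    hole = _resolve_hole(action.chosen_hole, lit, rng)
    if hole == lit:
        events.append(_ev(t_poke, "correct_poke", hole=hole))
        next_avail = rewarded(t_poke)
        record = make_record("correct", hole=hole,
                             correct_latency=action.response_latency,
                             magazine_latency=action.magazine_latency)
        return record, events, next_avail
    events.append(_ev(t_poke, "incorrect_poke", hole=hole))
    if stage.punish_incorrect:
        next_avail = timeout(t_poke)
    else:
        next_avail = t_poke
    return make_record("incorrect", hole=hole), events, next_avail


# ---------------------------------------------------------------------------
# Access windows


def _in_window(t: float, access: AccessWindow, lc: LightCycle,
               start_clock: float) -> bool:
    if access.mode == "unlimited":
        return True
    clock_h = (start_clock + t / 3600.0) % 24.0
    since_dark = (clock_h - lc.lights_off_clock) % 24.0
    lo = access.window_start_offset
    return lo <= since_dark < lo + access.window_duration


def _next_window_open(t: float, access: AccessWindow, lc: LightCycle,
                      start_clock: float) -> float:
    clock_h = (start_clock + t / 3600.0) % 24.0
    since_dark = (clock_h - lc.lights_off_clock) % 24.0
    lo = access.window_start_offset
    if since_dark < lo:
        dt_h = lo - since_dark
    else:
        dt_h = 24.0 - since_dark + lo
    return t + dt_h * 3600.0


# ---------------------------------------------------------------------------
# Session runner


def run_session(
    config: ProtocolConfig,
    agent,
    *,
    seed: int,
    subject_id: str = "S0",
    start_t: float = 0.0,
    start_clock: Optional[float] = None,
    horizon_s: Optional[float] = None,
    max_trials: Optional[int] = None,
    initial_stage: int = 0,
    challenge: Optional[ChallengeSpec] = None,
    stop_on_complete: bool = True,
    freeze_stage: bool = False,
    no_immediate_repeat: bool = False,
):
    """Simulate a session (or a multi-day run) and return its EventLog.

    Trials start only while the access window is open; a trial in progress
    at window close runs to completion, flagged ``spans_window_close`` in
    its start event's detail. Stage advancement fires immediately on a
    criterion pass or quota completion. With ``challenge`` set (or present
    in the config), per-trial ITI or SD is drawn from the challenge support
    and stage advancement is suspended for the session.

    ``horizon_s`` bounds trial starts to ``[start_t, start_t + horizon_s)``;
    ``max_trials`` bounds the trial count; at least one bound (or a finite
    ladder with ``stop_on_complete``) must make the run finite.
    """
    from .eventlog_io import EventLog  # local import: io layer depends on us

    if start_clock is None:
        start_clock = config.light_cycle.lights_off_clock
    challenge = challenge if challenge is not None else config.challenge
    if challenge is not None and max_trials is None and \
            challenge.session_quota is not None:
        max_trials = challenge.session_quota

    rng = np.random.default_rng(seed)
    lc = config.light_cycle
    access = config.access
    t_limit = None if horizon_s is None else start_t + horizon_s

    events: List[Event] = [_ev(start_t, "session_open", subject=subject_id,
                               protocol=config.name)]
    records: List[TrialRecord] = []
    stage_idx = initial_stage
    stage_hist: List[TrialRecord] = []
    trial_index = 0
    pellets_today = 0
    current_day = _day(start_t)
    recent_holes: List[int] = []
    t_avail = start_t
    t_last = start_t
    completed = False
    ended_by_horizon = False

    while True:
        if max_trials is not None and trial_index >= max_trials:
            break
        if stage_idx >= len(config.stages):
            break
        stage = config.stages[stage_idx]

        iti = stage.draw_iti(rng)
        sd = stage.sd
        if challenge is not None:
            values = list(challenge.values)
            drawn = float(values[rng.integers(len(values))])
            if challenge.kind == "var_iti":
                iti = drawn
            elif challenge.kind == "var_sd":
                sd = drawn
            else:
                raise ValueError(f"unknown challenge kind {challenge.kind!r}")

        # Find a trial start inside the access window (re-querying the agent
        # after each deferral so time-dependent modulation stays honest).
        t_start = None
        action = None
        for _ in range(10_000):
            if _in_window(t_avail, access, lc, start_clock):
                action = agent.decide(
                    stage, t_avail, lc, rng,
                    iti=iti, sd=sd,
                    start_clock=start_clock,
                    pellets_today=pellets_today,
                )
                cand = t_avail + action.initiate_delay
                if _in_window(cand, access, lc, start_clock):
                    t_start = cand
                    break
                t_avail = _next_window_open(cand, access, lc, start_clock)
            else:
                t_avail = _next_window_open(t_avail, access, lc, start_clock)
            if t_limit is not None and t_avail >= t_limit:
                break
        if t_start is None or (t_limit is not None and t_start >= t_limit):
            ended_by_horizon = True
            break

        if _day(t_start) != current_day:
            current_day = _day(t_start)
            pellets_today = 0

        in_dark = lc.is_dark((start_clock + t_start / 3600.0) % 24.0)
        record, trial_events, t_avail = run_trial(
            stage, action, t_start, rng,
            iti=iti, sd=sd,
            trial_index=trial_index,
            in_dark=in_dark,
            recent_holes=recent_holes,
            no_immediate_repeat=no_immediate_repeat,
        )
        if not _in_window(t_avail, access, lc, start_clock) and \
                access.mode == "restricted":
            trial_events[0].detail["spans_window_close"] = \
                not _in_window(trial_events[-1].t, access, lc, start_clock)
        events.extend(trial_events)
        records.append(record)
        t_last = trial_events[-1].t
        trial_index += 1
        if record.outcome == "correct":
            pellets_today += 1
        if record.hole is not None:
            recent_holes = [record.hole]

        if challenge is not None or freeze_stage:
            continue  # challenge / frozen baseline sessions never advance

        stage_hist.append(record)
        advanced = False
        if stage.fixed_trial_quota is not None:
            advanced = len(stage_hist) >= stage.fixed_trial_quota
            metrics = None
        else:
            advanced, metrics = evaluate_criterion(stage_hist, stage.criterion)
            events.append(
                _ev(t_last, "criterion_evaluated",
                    stage_id=stage.stage_id,
                    window_len=stage.criterion.window_len,
                    n_window=metrics.n_window,
                    accuracy_pct=metrics.accuracy_pct,
                    omission_pct=metrics.omission_pct,
                    started_in_stage=metrics.started_in_stage,
                    correct_in_stage=metrics.correct_in_stage,
                    passed=advanced)
            )
        if advanced:
            next_stage = config.stages[stage_idx + 1] if \
                stage_idx + 1 < len(config.stages) else None
            detail = dict(
                stage_id=(next_stage.stage_id if next_stage is not None
                          else stage.stage_id + 1),
                from_stage=stage.stage_id,
                trials_in_stage=len(stage_hist),
            )
            if metrics is not None:
                detail["window_accuracy_pct"] = metrics.accuracy_pct
                detail["window_omission_pct"] = metrics.omission_pct
            if next_stage is None:
                detail["ladder_complete"] = True
            events.append(_ev(t_last, "stage_advanced", **detail))
            stage_idx += 1
            stage_hist = []
            if stage_idx >= len(config.stages):
                completed = True
                if stop_on_complete:
                    break

    t_close = t_last
    if ended_by_horizon and t_limit is not None:
        # The window/horizon expired; a trial in progress may have run past
        # it, in which case the log closes at that trial's last event.
        t_close = max(t_last, t_limit)
    events.append(_ev(t_close, "session_close", n_trials=trial_index,
                      completed=completed))

    header = {
        "schema_version": 1,
        "protocol": config.name,
        "subject": subject_id,
        "seed": int(seed),
        "start_clock": float(start_clock),
        "lights_off_clock": float(lc.lights_off_clock),
        "dark_duration": float(lc.dark_duration),
    }
    return EventLog(header=header, events=events)
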