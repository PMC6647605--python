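"""High-level experiment designs built on the engine.

These functions reproduce the study designs end to end: full training runs
to stable baseline, variable-ITI / variable-SD challenge sessions, and
Latin-square crossover drug studies analyzed in 30-min blocks. The CLI is a
thin wrapper over this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .agent import AgentParams, DrugEffect, StochasticAgent, latin_square_schedule
from .engine import run_session
from .eventlog_io import EventLog, events_to_trials, trials_to_frame
from .metrics import block_split, summarize
from .protocol import ChallengeSpec, ProtocolConfig

__all__ = [
    "TrainingSummary",
    "subject_seed",
    "run_training",
    "training_summary",
    "run_challenge_session",
    "run_drug_study",
    "metrics_row",
    "VAR_ITI_VALUES",
    "VAR_SD_VALUES",
    "UA_CHALLENGE_QUOTA",
]

#: Challenge-session supports: variable inter-trial intervals and variable
#: stimulus durations (seconds), drawn uniformly per trial.
VAR_ITI_VALUES = (5.0, 7.5, 12.5)
VAR_SD_VALUES = (0.2, 0.5, 1.0)
#: Unlimited-access challenge sessions run a block of this many trials;
#: time-restricted sessions are bounded by the 2.5-h access window instead.
UA_CHALLENGE_QUOTA = 500

TRAINING_HORIZON_DAYS = 60.0


@dataclass(frozen=True)
class TrainingSummary:
    subject: str
    completed: bool
    days_to_criterion: Optional[float]  # fractional days to ladder end
    trials_to_criterion: Optional[int]
    trials_per_stage: Dict[int, int] = field(default_factory=dict)
    advancement_accuracies: List[float] = field(default_factory=list)


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Stable per-subject seed from a master seed via a counter scheme.

    Uses ``SeedSequence([master, index])`` so adding subjects never perturbs
    the streams of existing ones. Result fits in 31 bits.
    """
    ss = np.random.SeedSequence([int(master_seed), int(subject_index)])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def run_training(
    config: ProtocolConfig,
    agent,
    seed: int,
    *,
    subject_id: str = "S0",
    horizon_days: float = TRAINING_HORIZON_DAYS,
) -> EventLog:
    """Run a subject through the full stage ladder (or until the horizon)."""
    return run_session(
        config, agent, seed=seed, subject_id=subject_id,
        horizon_s=horizon_days * 86_400.0, stop_on_complete=True,
    )


def training_summary(log: EventLog) -> TrainingSummary:
    """Days/trials to criterion and per-stage trial counts from a log."""
    advanced = [ev for ev in log.events if ev.kind == "stage_advanced"]
    close = log.events[-1]
    completed = any(ev.detail.get("ladder_complete") for ev in advanced)
    per_stage = {ev.detail["from_stage"]: ev.detail["trials_in_stage"]
                 for ev in advanced}
    accs = [ev.detail["window_accuracy_pct"] for ev in advanced
            if ev.detail.get("window_accuracy_pct") is not None]
    days = trials = None
    if completed:
        t_done = advanced[-1].t
        days = t_done / 86_400.0
        trials = sum(per_stage.values())
    return TrainingSummary(
        subject=log.header.get("subject", "?"),
        completed=completed,
        days_to_criterion=days,
        trials_to_criterion=trials,
        trials_per_stage=per_stage,
        advancement_accuracies=accs,
    )


def _final_stage_index(config: ProtocolConfig) -> int:
    return len(config.stages) - 1


def run_challenge_session(
    config: ProtocolConfig,
    agent,
    seed: int,
    kind: str,
    *,
    subject_id: str = "S0",
    values: Optional[Sequence[float]] = None,
) -> EventLog:
    """One challenge session at the final (baseline) stage.

    ``kind`` is ``var_iti`` or ``var_sd``. Unlimited-access protocols run a
    500-trial block; restricted protocols run one access window (the engine
    enforces it) within a 24-h horizon.
    """
    if kind not in ("var_iti", "var_sd"):
        raise ValueError(f"unknown challenge kind {kind!r}")
    if values is None:
        values = VAR_ITI_VALUES if kind == "var_iti" else VAR_SD_VALUES
    restricted = config.access.mode == "restricted"
    challenge = ChallengeSpec(
        kind=kind, values=tuple(values),
        session_quota=None if restricted else UA_CHALLENGE_QUOTA,
    )
    return run_session(
        config, agent, seed=seed, subject_id=subject_id,
        initial_stage=_final_stage_index(config),
        challenge=challenge,
        horizon_s=86_400.0 if restricted else 7 * 86_400.0,
    )


def run_baseline_session(
    config: ProtocolConfig,
    agent,
    seed: int,
    *,
    subject_id: str = "S0",
    horizon_s: float = 86_400.0,
    max_trials: Optional[int] = None,
) -> EventLog:
    """A frozen-stage session at the final SD for baseline performance."""
    return run_session(
        config, agent, seed=seed, subject_id=subject_id,
        initial_stage=_final_stage_index(config),
        freeze_stage=True, horizon_s=horizon_s, max_trials=max_trials,
    )


def metrics_row(log: EventLog, **extra) -> dict:
    """One flat metrics record (summarize + identifiers) for report tables."""
    sm = summarize(events_to_trials(log))
    row = {"subject": log.header.get("subject"),
           "protocol": log.header.get("protocol"), **extra}
    row.update(vars(sm))
    return row


def run_drug_study(
    config: ProtocolConfig,
    agent_params: Dict[str, AgentParams],
    doses: Sequence[float],
    effect_template: DrugEffect,
    seed: int,
    *,
    reference_dose: Optional[float] = None,
    injection_lead_s: float = 20.0 * 60.0,
    block_minutes: float = 30.0,
    session_hours: float = 2.5,
    challenge_kind: str = "var_iti",
) -> pd.DataFrame:
    """Latin-square crossover dosing study, block-wise metrics table.

    Each subject receives each dose once (cyclic Latin square over the
    dosing-day positions). A dosed session is one access window of
    ``session_hours`` run under the variable-ITI challenge, with the drug
    effect scaled linearly by dose relative to ``reference_dose`` (default:
    the largest dose) and onset ``injection_lead_s`` before the session
    (injection 20 min before dark onset). Returns a long-format table with
    one row per subject x dose x 30-min block, ready for the dose x time
    repeated-measures ANOVA.
    """
    doses = list(doses)
    if len(doses) < 2:
        raise ValueError("need at least 2 doses")
    if reference_dose is None:
        reference_dose = max(d for d in doses) or 1.0
    subjects = list(agent_params)
    schedule = latin_square_schedule(doses, len(subjects))
    challenge = ChallengeSpec(
        kind=challenge_kind,
        values=VAR_ITI_VALUES if challenge_kind == "var_iti" else VAR_SD_VALUES,
    )
    rows = []
    for si, (sid, order) in enumerate(zip(subjects, schedule)):
        for day_pos, dose in enumerate(order):
            eff = effect_template.scaled(dose / reference_dose)
            eff = DrugEffect(**{**vars(eff), "dose": dose,
                                "onset_t": -injection_lead_s})
            agent = StochasticAgent(agent_params[sid], effects=(eff,))
            log = run_session(
                config, agent,
                seed=subject_seed(seed, si * len(doses) + day_pos),
                subject_id=sid,
                initial_stage=_final_stage_index(config),
                challenge=challenge,
                horizon_s=session_hours * 3600.0,
            )
            trials = trials_to_frame(events_to_trials(log))
            blocks = block_split(trials, block_minutes, 0.0,
                                 n_blocks=int(session_hours * 60 /
                                              block_minutes))
            for bi, blk in enumerate(blocks):
                sm = summarize(blk)
                rows.append({"subject": sid, "dose": dose,
                             "block": bi + 1, **vars(sm)})
    return pd.DataFrame(rows)
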