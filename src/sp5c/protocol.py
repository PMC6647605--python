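"""Task configuration for the self-paced 5-choice serial reaction time task.

A protocol is a ladder of training stages plus a trial-availability window
and a light cycle. Three presets are shipped:

``UA``
    Unlimited access: trials can be initiated 24 h/day.
``TR``
    Time-restricted: trials only during the first 2.5 h of the dark phase.
``CT``
    Conventional training: daily 30-min sessions, no eat-interval, no
    houselight during time-outs.

UA and TR differ solely in trial availability; all stage rules are shared.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import yaml

__all__ = [
    "LightCycle",
    "AccessWindow",
    "CriterionSpec",
    "StageSpec",
    "ChallengeSpec",
    "ProtocolConfig",
    "build_preset",
    "validate",
    "config_to_dict",
    "config_from_dict",
    "save_config",
    "load_config",
    "UNBOUNDED",
    "DEFAULT_SD_LADDER",
]

#: Sentinel stimulus duration for "light stays on until a response".
UNBOUNDED = math.inf

#: Default stimulus-duration shaping ladder (seconds): 16 s titrated down in
#: five steps to 1 s. Intermediate values follow conventional halving steps
#: with a 1.5-s step before the final 1-s stage.
DEFAULT_SD_LADDER = (16.0, 8.0, 4.0, 2.0, 1.5, 1.0)

STAGE_KINDS = ("magazine", "five_lit", "single_cue_untimed", "sd_limited")


@dataclass(frozen=True)
class LightCycle:
    """12-h light/dark cycle; clock times in decimal hours of day."""

    lights_off_clock: float = 12.0
    dark_duration: float = 12.0

    def is_dark(self, clock_hours: float) -> bool:
        """True if the given time of day falls in the dark phase."""
        since_off = (clock_hours - self.lights_off_clock) % 24.0
        return since_off < self.dark_duration


@dataclass(frozen=True)
class AccessWindow:
    """When trials may be initiated.

    ``unlimited`` ignores offset/duration; ``restricted`` opens the window
    ``window_start_offset`` hours after dark onset for ``window_duration``
    hours, each day.
    """

    mode: str = "unlimited"
    window_start_offset: float = 0.0
    window_duration: float = 0.0


@dataclass(frozen=True)
class CriterionSpec:
    """Sliding-window stage-advancement rule.

    Advancement requires ``min_started`` started trials in the stage, window
    accuracy strictly above ``accuracy_gt`` %, and either window omissions
    strictly below ``omission_lt`` % or more than ``correct_alt_gt`` correct
    trials accumulated in the stage. Window metrics are computed over the
    last ``window_len`` trials.
    """

    window_len: int = 20
    min_started: int = 50
    accuracy_gt: float = 80.0
    omission_lt: float = 20.0
    correct_alt_gt: int = 200


@dataclass(frozen=True)
class StageSpec:
    """One training stage's trial rules.

    Exactly one of ``fixed_trial_quota`` / ``criterion`` governs advancement.
    ``sd`` is seconds, or ``math.inf`` for lights-on-until-response, or None
    where no cue is presented (magazine stage). ``iti`` is a fixed value in
    seconds, a list of values drawn uniformly per trial, or None for no ITI.
    """

    stage_id: int
    kind: str
    sd: Optional[float] = None
    iti: Union[float, Sequence[float], None] = None
    limited_hold: float = 2.0
    timeout: float = 5.0
    houselight_on_timeout: bool = True
    punish_incorrect: bool = True
    eat_interval: float = 5.0
    fixed_trial_quota: Optional[int] = None
    criterion: Optional[CriterionSpec] = None

    def draw_iti(self, rng) -> Optional[float]:
        if self.iti is None:
            return None
        if isinstance(self.iti, (int, float)):
            return float(self.iti)
        values = list(self.iti)
        return float(values[rng.integers(len(values))])


@dataclass(frozen=True)
class ChallengeSpec:
    """A challenge-session design: per-trial variation of ITI or SD.

    ``kind`` is ``var_iti`` or ``var_sd``; ``values`` is the support the
    varied parameter is drawn from, uniformly per trial. ``session_quota``
    is a trial count (unlimited access) — time-restricted sessions are
    bounded by the access window instead.
    """

    kind: str
    values: tuple
    session_quota: Optional[int] = None


@dataclass(frozen=True)
class ProtocolConfig:
    name: str
    stages: tuple
    access: AccessWindow = field(default_factory=AccessWindow)
    light_cycle: LightCycle = field(default_factory=LightCycle)
    challenge: Optional[ChallengeSpec] = None

    @property
    def final_stage(self) -> StageSpec:
        return self.stages[-1]


def _standard_stages(
    *,
    eat_interval: float,
    houselight_on_timeout: bool,
    sd_ladder: Sequence[float] = DEFAULT_SD_LADDER,
) -> tuple:
    """Build the shared training ladder.

    Magazine training (50 pellet deliveries at variable 4/8/16/32-s ITI),
    five-lit-holes stage (50 trials), single-cue untimed stage (light stays
    on, incorrect pokes unpunished, criterion-based advancement), then the
    SD-limited ladder, and a final baseline block at the last SD governed by
    a second application of the same criterion.
    """
    crit = CriterionSpec()
    stages = [
        StageSpec(
            stage_id=0,
            kind="magazine",
            iti=(4.0, 8.0, 16.0, 32.0),
            eat_interval=0.0,  # pellet collection triggers the next trial
            houselight_on_timeout=houselight_on_timeout,
            fixed_trial_quota=50,
        ),
        StageSpec(
            stage_id=1,
            kind="five_lit",
            sd=UNBOUNDED,
            iti=None,
            eat_interval=eat_interval,
            houselight_on_timeout=houselight_on_timeout,
            fixed_trial_quota=50,
        ),
        StageSpec(
            stage_id=2,
            kind="single_cue_untimed",
            sd=UNBOUNDED,
            iti=5.0,
            punish_incorrect=False,
            eat_interval=eat_interval,
            houselight_on_timeout=houselight_on_timeout,
            criterion=crit,
        ),
    ]
    next_id = 3
    for sd in sd_ladder:
        stages.append(
            StageSpec(
                stage_id=next_id,
                kind="sd_limited",
                sd=float(sd),
                iti=5.0,
                eat_interval=eat_interval,
                houselight_on_timeout=houselight_on_timeout,
                criterion=crit,
            )
        )
        next_id += 1
    # Baseline block: same criterion applied a second time at the final SD.
    stages.append(
        StageSpec(
            stage_id=next_id,
            kind="sd_limited",
            sd=float(sd_ladder[-1]),
            iti=5.0,
            eat_interval=eat_interval,
            houselight_on_timeout=houselight_on_timeout,
            criterion=crit,
        )
    )
    return tuple(stages)


def build_preset(variant: str) -> "ProtocolConfig":
    """Return a validated built-in protocol (``UA``, ``TR`` or ``CT``)."""
    variant = variant.upper()
    if variant == "UA":
        config = ProtocolConfig(
            name="UA",
            stages=_standard_stages(eat_interval=5.0, houselight_on_timeout=True),
            access=AccessWindow(mode="unlimited"),
        )
    elif variant == "TR":
        config = ProtocolConfig(
            name="TR",
            stages=_standard_stages(eat_interval=5.0, houselight_on_timeout=True),
            access=AccessWindow(
                mode="restricted", window_start_offset=0.0, window_duration=2.5
            ),
        )
    elif variant == "CT":
        # Conventional training: daily 30-min sessions, immediate next trial
        # after reward, houselight stays off during time-outs.
        config = ProtocolConfig(
            name="CT",
            stages=_standard_stages(eat_interval=0.0, houselight_on_timeout=False),
            access=AccessWindow(
                mode="restricted", window_start_offset=0.0, window_duration=0.5
            ),
        )
    else:
        raise ValueError(f"unknown protocol variant: {variant!r}")
    violations = validate(config)
    assert not violations, violations
    return config


def validate(config: ProtocolConfig) -> list:
    """Check every type invariant; return violation descriptions (no raise)."""
    v: list = []
    lc = config.light_cycle
    if not (0.0 <= lc.lights_off_clock < 24.0):
        v.append("light_cycle.lights_off_clock: must be in [0, 24)")
    if not (0.0 < lc.dark_duration < 24.0):
        v.append("light_cycle.dark_duration: must be in (0, 24)")
    aw = config.access
    if aw.mode not in ("unlimited", "restricted"):
        v.append(f"access.mode: unknown mode {aw.mode!r}")
    elif aw.mode == "restricted" and not aw.window_duration > 0:
        v.append("access.window_duration: must be > 0 when restricted")
    if not config.stages:
        v.append("stages: empty stage list")
    ids = [s.stage_id for s in config.stages]
    if ids != sorted(set(ids)):
        v.append("stages: stage_id values must be strictly increasing")
    sd_seq = [
        s.sd for s in config.stages if s.kind == "sd_limited" and s.sd is not None
    ]
    if any(b > a for a, b in zip(sd_seq, sd_seq[1:])):
        v.append("stages: sd_limited ladder must have non-increasing sd values")
    for s in config.stages:
        tag = f"stages[{s.stage_id}]"
        if s.kind not in STAGE_KINDS:
            v.append(f"{tag}.kind: unknown kind {s.kind!r}")
        if (s.fixed_trial_quota is None) == (s.criterion is None):
            v.append(f"{tag}: exactly one of fixed_trial_quota/criterion required")
        if s.kind == "sd_limited" and not (s.sd is not None and s.sd > 0):
            v.append(f"{tag}.sd: must be > 0 for sd_limited stage")
        if s.fixed_trial_quota is not None and s.fixed_trial_quota < 1:
            v.append(f"{tag}.fixed_trial_quota: must be >= 1")
        if s.limited_hold < 0 or s.timeout < 0 or s.eat_interval < 0:
            v.append(f"{tag}: limited_hold/timeout/eat_interval must be >= 0")
        c = s.criterion
        if c is not None:
            if c.window_len < 1:
                v.append(f"{tag}.criterion.window_len: must be >= 1")
            if c.min_started < c.window_len:
                v.append(f"{tag}.criterion.min_started: must be >= window_len")
            for name in ("accuracy_gt", "omission_lt"):
                val = getattr(c, name)
                if not (0.0 <= val <= 100.0):
                    v.append(f"{tag}.criterion.{name}: must be in [0, 100]")
    ch = config.challenge
    if ch is not None:
        if ch.kind not in ("var_iti", "var_sd"):
            v.append(f"challenge.kind: unknown kind {ch.kind!r}")
        if not ch.values:
            v.append("challenge.values: empty support")
    return v


# ---------------------------------------------------------------------------
# Serialization (YAML; the same dict form is used by the preset data files)


def _none_if_inf(x):
    if x is None:
        return None
    return "unbounded" if math.isinf(x) else x


def _inf_if_marked(x):
    if x == "unbounded":
        return UNBOUNDED
    return x


def config_to_dict(config: ProtocolConfig) -> dict:
    d = {
        "name": config.name,
        "light_cycle": dataclasses.asdict(config.light_cycle),
        "access": dataclasses.asdict(config.access),
        "stages": [],
    }
    for s in config.stages:
        sd = dataclasses.asdict(s)
        sd["sd"] = _none_if_inf(s.sd)
        if isinstance(s.iti, tuple):
            sd["iti"] = list(s.iti)
        d["stages"].append(sd)
    if config.challenge is not None:
        d["challenge"] = {
            "kind": config.challenge.kind,
            "values": list(config.challenge.values),
            "session_quota": config.challenge.session_quota,
        }
    return d


def config_from_dict(d: dict) -> ProtocolConfig:
    stages = []
    for sd in d["stages"]:
        sd = dict(sd)
        sd["sd"] = _inf_if_marked(sd.get("sd"))
        if isinstance(sd.get("iti"), list):
            sd["iti"] = tuple(sd["iti"])
        crit = sd.get("criterion")
        if crit is not None:
            sd["criterion"] = CriterionSpec(**crit)
        stages.append(StageSpec(**sd))
    challenge = None
    if d.get("challenge") is not None:
        ch = d["challenge"]
        challenge = ChallengeSpec(
            kind=ch["kind"],
            values=tuple(ch["values"]),
            session_quota=ch.get("session_quota"),
        )
    return ProtocolConfig(
        name=d["name"],
        stages=tuple(stages),
        access=AccessWindow(**d.get("access", {})),
        light_cycle=LightCycle(**d.get("light_cycle", {})),
        challenge=challenge,
    )


def save_config(config: ProtocolConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> ProtocolConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))
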