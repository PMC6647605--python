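"""Event-log serialization and trial-table reconstruction.

The native interchange format is JSON Lines: the first line holds the
header object ``{"header": {...}}``, every following line one event
``{"t": ..., "day": ..., "kind": ..., "detail": {...}}``. A CSV dialect
with fixed column order ``t, day, kind, detail`` (detail JSON-encoded) is
provided for spreadsheet users; the header travels as a ``#``-prefixed
JSON comment line. Both dialects round-trip losslessly.

``events_to_trials`` rebuilds the per-trial table (outcome, latencies,
realized ITI/SD, dark-phase flag) from the raw event stream — the analysis
pipeline never touches engine internals, only logs.
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Union

import pandas as pd

from .engine import EVENT_KINDS, Event, TrialRecord
from .protocol import LightCycle

__all__ = [
    "EventLog",
    "write_log",
    "read_log",
    "events_to_trials",
    "trials_to_frame",
    "write_trials_csv",
]

SCHEMA_VERSION = 1

_TERMINAL = ("correct_poke", "incorrect_poke", "omission", "premature_poke")
_OUTCOME_OF = {
    "correct_poke": "correct",
    "incorrect_poke": "incorrect",
    "omission": "omission",
    "premature_poke": "premature",
}


@dataclass
class EventLog:
    header: dict
    events: List[Event] = field(default_factory=list)

    def validate(self) -> None:
        if "schema_version" not in self.header:
            raise ValueError("event log header lacks schema_version")
        if self.header["schema_version"] != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema version {self.header['schema_version']!r}"
                f" (supported: {SCHEMA_VERSION})"
            )
        t_prev = -math.inf
        for i, ev in enumerate(self.events):
            if ev.t < t_prev:
                raise ValueError(f"non-monotone timestamp at event {i}")
            t_prev = ev.t
            if ev.kind not in EVENT_KINDS:
                warnings.warn(f"unknown event kind {ev.kind!r} at event {i}",
                              stacklevel=2)


def _encode_event(ev: Event, index: int) -> dict:
    try:
        json.dumps(ev.detail)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"unserializable detail value in event {index}: {exc}"
        ) from exc
    return {"t": ev.t, "day": ev.day, "kind": ev.kind, "detail": ev.detail}


def write_log(log: EventLog, stream=None, dialect: str = "jsonl") -> Optional[str]:
    """Serialize a log; returns the text when ``stream`` is None."""
    own = stream is None
    out = io.StringIO() if own else stream
    if dialect == "jsonl":
        out.write(json.dumps({"header": log.header}, sort_keys=True) + "\n")
        for i, ev in enumerate(log.events):
            out.write(json.dumps(_encode_event(ev, i), sort_keys=True) + "\n")
    elif dialect == "csv":
        out.write("# " + json.dumps({"header": log.header}, sort_keys=True) + "\n")
        writer = csv.writer(out, lineterminator="\n")
        writer.writerow(["t", "day", "kind", "detail"])
        for i, ev in enumerate(log.events):
            enc = _encode_event(ev, i)
            writer.writerow([repr(ev.t), ev.day, ev.kind,
                             json.dumps(enc["detail"], sort_keys=True)])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return out.getvalue() if own else None


def read_log(source: Union[str, io.TextIOBase]) -> EventLog:
    """Parse a log from text or a text stream (dialect auto-detected)."""
    text = source.read() if hasattr(source, "read") else source
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty event log")
    if lines[0].startswith("#"):
        return _read_csv(lines)
    return _read_jsonl(lines)


def _parse_header(obj: dict, where: str) -> dict:
    if not isinstance(obj, dict) or "header" not in obj:
        raise ValueError(f"{where}: expected a header object")
    return obj["header"]


def _read_jsonl(lines) -> EventLog:
    try:
        header = _parse_header(json.loads(lines[0]), "line 1")
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed header line 1: {exc}") from exc
    events = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed event line {lineno}: {exc}") from exc
        events.append(Event(t=float(obj["t"]), day=int(obj["day"]),
                            kind=obj["kind"], detail=obj.get("detail", {})))
    log = EventLog(header=header, events=events)
    log.validate()
    return log


def _read_csv(lines) -> EventLog:
    header = _parse_header(json.loads(lines[0].lstrip("# ")), "line 1")
    rows = list(csv.reader(lines[1:]))
    if not rows or rows[0] != ["t", "day", "kind", "detail"]:
        raise ValueError("line 2: expected CSV column header t,day,kind,detail")
    events = []
    for lineno, row in enumerate(rows[1:], start=3):
        if not row:
            continue
        try:
            events.append(Event(t=float(row[0]), day=int(row[1]), kind=row[2],
                                detail=json.loads(row[3])))
        except (ValueError, IndexError, json.JSONDecodeError) as exc:
            raise ValueError(f"malformed event line {lineno}: {exc}") from exc
    log = EventLog(header=header, events=events)
    log.validate()
    return log


def events_to_trials(log: EventLog) -> List[TrialRecord]:
    """Reconstruct one TrialRecord per trial_start from the event stream.

    A trial left dangling at the end of the log is returned flagged
    ``incomplete`` (outcome ``"incomplete"``); metrics ignore such records.
    """
    log.validate()
    lc = LightCycle(
        lights_off_clock=log.header.get("lights_off_clock", 12.0),
        dark_duration=log.header.get("dark_duration", 12.0),
    )
    start_clock = log.header.get("start_clock", lc.lights_off_clock)

    records: List[TrialRecord] = []
    cur: Optional[dict] = None

    def close(outcome, hole=None, correct_latency=None, magazine_latency=None,
              incomplete=False):
        nonlocal cur
        clock_h = (start_clock + cur["t_start"] / 3600.0) % 24.0
        records.append(TrialRecord(
            trial_index=cur["trial_index"],
            stage_id=cur["stage_id"],
            t_start=cur["t_start"],
            outcome=outcome,
            hole=hole,
            iti_used=cur.get("iti"),
            sd_used=cur.get("sd"),
            correct_latency=correct_latency,
            magazine_latency=magazine_latency,
            in_dark_phase=lc.is_dark(clock_h),
            incomplete=incomplete,
        ))
        cur = None

    pending: Optional[dict] = None  # closed-outcome info awaiting reward pickup
    for ev in log.events:
        if ev.kind == "trial_start":
            if cur is not None:
                close("incomplete", incomplete=True)
            cur = {
                "t_start": ev.t,
                "trial_index": ev.detail.get("trial_index", len(records)),
                "stage_id": ev.detail.get("stage_id", -1),
                "iti": ev.detail.get("iti"),
                "sd": ev.detail.get("sd"),
            }
            pending = None
        elif cur is None:
            continue
        elif ev.kind == "stimulus_on":
            cur["t_stim"] = ev.t
        elif ev.kind == "correct_poke":
            pending = {"hole": ev.detail.get("hole"),
                       "latency": ev.t - cur.get("t_stim", ev.t),
                       "t_poke": ev.t}
        elif ev.kind == "reward_collected":
            if pending is not None:
                close("correct", hole=pending["hole"],
                      correct_latency=pending["latency"],
                      magazine_latency=ev.t - pending["t_poke"])
                pending = None
            else:  # magazine stage: no poke, pellet auto-delivered
                close("correct", magazine_latency=ev.t - cur.get("t_pellet", ev.t))
        elif ev.kind == "pellet_delivered":
            cur.setdefault("t_pellet", ev.t)
        elif ev.kind == "incorrect_poke":
            close("incorrect", hole=ev.detail.get("hole"))
        elif ev.kind == "omission":
            close("omission")
        elif ev.kind == "premature_poke":
            close("premature")
    if cur is not None:
        close("incomplete", incomplete=True)
    return records


TRIAL_COLUMNS = [
    "trial_index", "stage_id", "t_start", "outcome", "hole", "iti_used",
    "sd_used", "correct_latency", "magazine_latency", "in_dark_phase",
    "incomplete",
]


def trials_to_frame(trials) -> pd.DataFrame:
    """Trial records as a DataFrame with the documented column order."""
    if isinstance(trials, pd.DataFrame):
        return trials
    return pd.DataFrame([vars(r) for r in trials], columns=TRIAL_COLUMNS)


def write_trials_csv(trials, path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)
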