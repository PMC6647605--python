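"""Behavioral parameters and session partitions for 5-CSRTT trial tables.

Definitions (all on completed trials):

* accuracy = 100 * #correct / (#correct + #incorrect) — omissions and
  prematures excluded from numerator and denominator; the operational
  measure of attention.
* %omissions, %prematures = 100 * #type / #total trials.
* correct-response latency: stimulus onset to correct poke, averaged over
  correct trials; magazine latency: correct poke to pellet collection.
* trials with magazine latency > 10 s are excluded from further analysis
  (default scope removes the whole trial from the analysis at hand; a
  latency-only scope is available).

Partitions: dark/light phase, consecutive 30-min blocks of a session, and
first-N-trials / first-H-hours prefixes. All metric functions accept either
a sequence of TrialRecord or the equivalent DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .eventlog_io import trials_to_frame

__all__ = [
    "SessionMetrics",
    "MAGAZINE_LATENCY_CUTOFF",
    "accuracy",
    "omission_pct",
    "premature_pct",
    "latency_summary",
    "apply_magazine_exclusion",
    "split_by_phase",
    "block_split",
    "first_n",
    "first_hours",
    "summarize",
]

#: Magazine-latency exclusion threshold in seconds (strict >).
MAGAZINE_LATENCY_CUTOFF = 10.0


@dataclass(frozen=True)
class SessionMetrics:
    n_started: int
    accuracy_pct: Optional[float]
    omission_pct: Optional[float]
    premature_pct: Optional[float]
    correct_latency_mean: Optional[float]
    magazine_latency_mean: Optional[float]
    n_latency_excluded: int


def _frame(trials) -> pd.DataFrame:
    df = trials_to_frame(trials)
    if "incomplete" in df.columns and len(df):
        df = df[~df["incomplete"].astype(bool)]
    return df


def accuracy(trials) -> Optional[float]:
    """Percent correct of responded (correct + incorrect) trials; None when
    no trial received a response."""
    df = _frame(trials)
    c = int((df["outcome"] == "correct").sum()) if len(df) else 0
    i = int((df["outcome"] == "incorrect").sum()) if len(df) else 0
    if c + i == 0:
        return None
    return 100.0 * c / (c + i)


def _pct_of_total(trials, outcome: str) -> Optional[float]:
    df = _frame(trials)
    n = len(df)
    if n == 0:
        return None
    return 100.0 * int((df["outcome"] == outcome).sum()) / n


def omission_pct(trials) -> Optional[float]:
    """Omitted trials as percent of all trials; None on an empty table."""
    return _pct_of_total(trials, "omission")


def premature_pct(trials) -> Optional[float]:
    """Premature trials as percent of all trials; None on an empty table."""
    return _pct_of_total(trials, "premature")


def latency_summary(
    trials, cutoff: float = MAGAZINE_LATENCY_CUTOFF
) -> Tuple[Optional[float], Optional[float], int]:
    """Mean correct-response and magazine latencies over correct trials.

    Magazine latencies strictly above ``cutoff`` are excluded from the
    magazine-latency mean; the count of such trials is returned. A latency
    of exactly ``cutoff`` is retained.
    """
    df = _frame(trials)
    correct = df[df["outcome"] == "correct"] if len(df) else df
    if len(correct) == 0:
        return None, None, 0
    resp = correct["correct_latency"].dropna()
    resp_mean = float(resp.mean()) if len(resp) else None
    mag = correct["magazine_latency"].dropna()
    kept = mag[mag <= cutoff]
    n_excluded = int((mag > cutoff).sum())
    mag_mean = float(kept.mean()) if len(kept) else None
    return resp_mean, mag_mean, n_excluded


def apply_magazine_exclusion(
    trials, scope: str = "whole-trial", cutoff: float = MAGAZINE_LATENCY_CUTOFF
) -> pd.DataFrame:
    """Drop trials with magazine latency > cutoff when scope='whole-trial';
    with scope='latency-only' the table is returned unchanged (the exclusion
    then only affects the magazine-latency mean)."""
    if scope not in ("whole-trial", "latency-only"):
        raise ValueError(f"unknown exclusion scope {scope!r}")
    df = _frame(trials)
    if scope == "latency-only" or len(df) == 0:
        return df
    mask = df["magazine_latency"].notna() & (df["magazine_latency"] > cutoff)
    return df[~mask]


def split_by_phase(trials) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(dark-phase subset, light-phase subset); disjoint, union = input."""
    df = _frame(trials)
    if len(df) == 0:
        return df, df.copy()
    dark = df["in_dark_phase"].astype(bool)
    return df[dark], df[~dark]


def block_split(
    trials, block_minutes: float, session_start: float,
    n_blocks: Optional[int] = None,
) -> List[pd.DataFrame]:
    """Partition by trial start time into consecutive half-open intervals
    ``[start + k*block, start + (k+1)*block)``; a trial exactly on a
    boundary joins the later block. ``n_blocks`` pads/limits the list (a
    2.5-h session at 30-min blocks yields exactly 5), defaulting to the
    span of the data.
    """
    if block_minutes <= 0:
        raise ValueError("block_minutes must be > 0")
    df = _frame(trials)
    width = block_minutes * 60.0
    if n_blocks is None:
        if len(df) == 0:
            return []
        last = float(df["t_start"].max())
        n_blocks = int((last - session_start) // width) + 1
    out = []
    for k in range(n_blocks):
        lo = session_start + k * width
        hi = lo + width
        if len(df) == 0:
            out.append(df.copy())
        else:
            out.append(df[(df["t_start"] >= lo) & (df["t_start"] < hi)])
    return out


def first_n(trials, n: int) -> pd.DataFrame:
    """The first ``n`` trials in table order (stable)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return _frame(trials).iloc[:n]


def first_hours(trials, hours: float, session_start: float) -> pd.DataFrame:
    """Trials starting within ``hours`` of ``session_start`` (half-open)."""
    df = _frame(trials)
    if len(df) == 0:
        return df
    return df[(df["t_start"] >= session_start)
              & (df["t_start"] < session_start + hours * 3600.0)]


def summarize(
    trials, exclusion_scope: str = "whole-trial",
    cutoff: float = MAGAZINE_LATENCY_CUTOFF,
) -> SessionMetrics:
    """Full per-session summary after the magazine-latency exclusion."""
    df = _frame(trials)
    _, _, n_excluded = latency_summary(df, cutoff)
    kept = apply_magazine_exclusion(df, exclusion_scope, cutoff)
    resp_mean, mag_mean, _ = latency_summary(df if exclusion_scope ==
                                             "latency-only" else kept, cutoff)
    return SessionMetrics(
        n_started=len(kept),
        accuracy_pct=accuracy(kept),
        omission_pct=omission_pct(kept),
        premature_pct=premature_pct(kept),
        correct_latency_mean=resp_mean,
        magazine_latency_mean=mag_mean,
        n_latency_excluded=n_excluded,
    )
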