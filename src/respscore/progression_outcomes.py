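"""Confirmed-progression time-to-event outcomes from visit-level scores.

Four endpoints are supported:

* EDSS progression — a 1.0-point increase when baseline EDSS <= 5.0, a
  0.5-point increase when baseline >= 5.5, confirmed at a scheduled visit
  at least ``confirm_window_days`` later (3 months by default).
* T25FW / 9HPT progression — worsening by at least 20% from baseline
  (times in seconds, higher is worse), confirmed the same way.
* SDMT progression — a drop of at least 4 points, confirmed at least
  ``sdmt_confirm_days`` later (6 months by default).

The event time is always the day of the *initial* qualifying worsening.
By default confirmation must be *sustained*: the worsening must hold at
every visit with an observed score from the initial visit through the
first scheduled visit at/after the confirmation window. A worsening seen
at the last available visit cannot be confirmed and yields censoring.
Visits where the relevant score is missing are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trial_io import OUTCOMES

#: visits CSV column used by each outcome
SCORE_COLUMN = {"EDSS": "edss", "T25FW": "t25fw", "9HPT": "hpt9", "SDMT": "sdmt"}

DEFAULT_CONFIRM_DAYS = 84
DEFAULT_SDMT_CONFIRM_DAYS = 168


@dataclass(frozen=True)
class ProgressionEvent:
    patient_id: str
    outcome: str
    time_days: int
    event: bool


def _confirmed_event(
    days: np.ndarray,
    values: np.ndarray,
    qualifies: Callable[[np.ndarray], np.ndarray],
    confirm_window_days: int,
    sustained: bool,
) -> tuple[int, bool]:
    """Generic confirmed-worsening scan; returns (time_days, event)."""
    worse = qualifies(values)
    n = len(days)
    for i in range(n):
        if not worse[i]:
            continue
        # first scheduled visit with an observed score at/after the window
        later = np.nonzero(days >= days[i] + confirm_window_days)[0]
        if later.size == 0:
            continue  # cannot be confirmed within follow-up
        j = later[0]
        if sustained:
            if worse[i : j + 1].all():
                return int(days[i]), True
        else:
            if worse[later].any():
                return int(days[i]), True
    return int(days[-1]), False


def _prepare(visits: pd.DataFrame, score_col: str) -> tuple[str, np.ndarray, np.ndarray]:
    if score_col not in visits.columns:
        raise ValueError(f"visits table lacks score column {score_col!r}")
    pid = str(visits["patient_id"].iloc[0])
    v = visits[["day", score_col]].dropna().sort_values("day")
    days = v["day"].to_numpy(dtype=int)
    if len(days) and len(np.unique(days)) != len(days):
        raise ValueError(f"duplicate visit days for patient {pid!r}")
    if len(days) == 0 or days[0] != 0:
        raise ValueError(f"patient {pid!r} has no day-0 {score_col} score")
    return pid, days, v[score_col].to_numpy(dtype=float)


def edss_progression(
    visits: pd.DataFrame,
    confirm_window_days: int = DEFAULT_CONFIRM_DAYS,
    sustained: bool = True,
) -> ProgressionEvent:
    """EDSS-step progression for one patient's visits."""
    pid, days, vals = _prepare(visits, "edss")
    baseline = vals[0]
    delta = 1.0 if baseline <= 5.0 else 0.5
    time, event = _confirmed_event(
        days, vals, lambda v: v >= baseline + delta, confirm_window_days, sustained
    )
    return ProgressionEvent(pid, "EDSS", time, event)


def percent_worsening_progression(
    visits: pd.DataFrame,
    score_field: str,
    pct: float = 0.20,
    confirm_window_days: int = DEFAULT_CONFIRM_DAYS,
    sustained: bool = True,
) -> ProgressionEvent:
    """>= pct worsening from baseline (T25FW / 9HPT; higher seconds = worse)."""
    outcome = {v: k for k, v in SCORE_COLUMN.items()}.get(score_field)
    if outcome not in ("T25FW", "9HPT"):
        raise ValueError(f"percent-worsening rule applies to t25fw/hpt9, not {score_field!r}")
    pid, days, vals = _prepare(visits, score_field)
    baseline = vals[0]
    if baseline <= 0:
        raise ValueError(f"non-positive baseline {score_field} for patient {pid!r}")
    threshold = baseline * (1.0 + pct)
    time, event = _confirmed_event(
        days, vals, lambda v: v >= threshold, confirm_window_days, sustained
    )
    return ProgressionEvent(pid, outcome, time, event)


def sdmt_progression(
    visits: pd.DataFrame,
    confirm_window_days: int = DEFAULT_SDMT_CONFIRM_DAYS,
    sustained: bool = True,
) -> ProgressionEvent:
    """SDMT worsening by >= 4 points, 6-month confirmed by default."""
    pid, days, vals = _prepare(visits, "sdmt")
    baseline = vals[0]
    time, event = _confirmed_event(
        days, vals, lambda v: v <= baseline - 4.0, confirm_window_days, sustained
    )
    return ProgressionEvent(pid, "SDMT", time, event)


def derive_events(
    visits: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOMES,
    confirm_window_days: int = DEFAULT_CONFIRM_DAYS,
    sdmt_confirm_days: int = DEFAULT_SDMT_CONFIRM_DAYS,
    sustained: bool = True,
    pct: float = 0.20,
) -> pd.DataFrame:
    """Apply the progression rules per patient; returns a long event table."""
    records = []
    for pid, group in visits.groupby("patient_id", sort=True):
        for outcome in outcomes:
            if outcome == "EDSS":
                ev = edss_progression(group, confirm_window_days, sustained)
            elif outcome in ("T25FW", "9HPT"):
                ev = percent_worsening_progression(
                    group, SCORE_COLUMN[outcome], pct, confirm_window_days, sustained
                )
            elif outcome == "SDMT":
                ev = sdmt_progression(group, sdmt_confirm_days, sustained)
            else:
                raise ValueError(f"unknown outcome {outcome!r}")
            records.append((ev.patient_id, ev.outcome, ev.time_days, int(ev.event)))
    return pd.DataFrame(records, columns=["patient_id", "outcome", "time_days", "event"])
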