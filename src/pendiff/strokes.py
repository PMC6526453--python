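"""From digital-pen strokes to analyzable trials.

A stroke log holds one checkbox mark per answered item: pen-down and pen-up
times (seconds since page start) plus which box was ticked. The response
time of item ``i`` on a page is defined as the pen-down time of item ``i``
minus the pen-up time of item ``i - 1``, which isolates item ``i``'s
processing from the motor completion of the previous mark. Slot 1 of every
page is the reference anchor and never receives an RT. A missing stroke
breaks the chain: the following item's RT is undefined as well (RTs are
never computed across gaps).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple, Union

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DataError
from .design import ExperimentDesign, StimulusSpec

__all__ = [
    "StrokeEvent",
    "TrialRecord",
    "schedule_to_frame",
    "strokes_to_trials",
    "trim_rts",
]

#: Default RT trimming window in seconds: responses faster than 250 ms or
#: slower than 3500 ms are treated as contaminants and eliminated.
TRIM_LO = 0.250
TRIM_HI = 3.500


@dataclass(frozen=True)
class StrokeEvent:
    """One checkbox mark of one participant."""

    participant_id: str
    session: int
    page: int
    slot: int
    checkbox: str  # "yes" | "no"
    pen_down: float  # seconds since page start
    pen_up: float

    def __post_init__(self):
        if self.pen_up < self.pen_down:
            raise DataError(
                f"pen_up before pen_down at ({self.participant_id}, "
                f"s{self.session} p{self.page} slot{self.slot})"
            )


@dataclass(frozen=True)
class TrialRecord:
    """One analyzable item: condition, response, and response time."""

    participant_id: str
    session: int
    page: int
    slot: int
    condition: str
    is_reference: bool
    is_practice: bool
    response: Optional[str]  # "word" | "nonword" | None (missing)
    rt: Optional[float]  # seconds, None for references / broken chains
    correct: Optional[bool]


def schedule_to_frame(schedule: Union[Iterable[StimulusSpec], pd.DataFrame]) -> pd.DataFrame:
    if isinstance(schedule, pd.DataFrame):
        return schedule
    return pd.DataFrame([s.__dict__ for s in schedule])


def _strokes_frame(strokes) -> pd.DataFrame:
    if isinstance(strokes, pd.DataFrame):
        return strokes
    return pd.DataFrame([s.__dict__ for s in strokes]).rename(
        columns={"pen_down": "pen_down_s", "pen_up": "pen_up_s"}
    )


def strokes_to_trials(
    strokes,
    schedule,
    n_practice_sessions: int = ExperimentDesign.n_practice_sessions,
) -> pd.DataFrame:
    """Derive the trial table from a stroke log and the stimulus schedule.

    Parameters
    ----------
    strokes
        DataFrame with columns ``participant_id, session, page, slot,
        checkbox, pen_down_s, pen_up_s`` (or an iterable of
        :class:`StrokeEvent`). May contain several participants.
    schedule
        The stimulus schedule (list of :class:`StimulusSpec` or DataFrame).
    n_practice_sessions
        Sessions ``<= n_practice_sessions`` are flagged as practice.

    Returns
    -------
    DataFrame with one row per (participant, scheduled item): columns
    ``participant_id, session, page, slot, condition, is_reference,
    is_practice, response, rt_s, correct``. Missing strokes yield missing
    responses; the item after a missing stroke has no RT either.
    """
    strokes = _strokes_frame(strokes).copy()
    sched = schedule_to_frame(schedule)[
        ["session", "page", "slot", "condition", "is_reference"]
    ]
    unknown = strokes.merge(sched, on=["session", "page", "slot"], how="left")
    if unknown["condition"].isna().any():
        bad = unknown[unknown["condition"].isna()].iloc[0]
        raise DataError(
            f"stroke references unscheduled item (session {bad['session']}, "
            f"page {bad['page']}, slot {bad['slot']})"
        )
    if (strokes["pen_up_s"] < strokes["pen_down_s"]).any():
        raise DataError("stroke with pen_up before pen_down")

    participants = strokes["participant_id"].unique()
    grid = sched.merge(pd.DataFrame({"participant_id": participants}), how="cross")
    df = grid.merge(
        strokes[["participant_id", "session", "page", "slot", "checkbox",
                 "pen_down_s", "pen_up_s"]],
        on=["participant_id", "session", "page", "slot"],
        how="left",
    )
    df = df.sort_values(["participant_id", "session", "page", "slot"]).reset_index(
        drop=True
    )
    prev_up = df.groupby(["participant_id", "session", "page"])["pen_up_s"].shift(1)
    rt = df["pen_down_s"] - prev_up
    rt[df["slot"] == 1] = np.nan  # references never get an RT

    neg = rt < 0
    if neg.any():
        bad = df[neg].iloc[0]
        raise DataError(
            f"negative RT at (participant {bad['participant_id']}, session "
            f"{bad['session']}, page {bad['page']}, slot {bad['slot']})"
        )

    response = df["checkbox"].map({"yes": "word", "no": "nonword"})
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "session": df["session"],
            "page": df["page"],
            "slot": df["slot"],
            "condition": df["condition"],
            "is_reference": df["is_reference"].astype(bool),
            "is_practice": df["session"] <= n_practice_sessions,
            "response": response,
            "rt_s": rt,
        }
    )
    out["correct"] = np.where(
        out["response"].notna(), out["response"] == out["condition"], np.nan
    )
    return out


def trim_rts(
    trials: pd.DataFrame, lo: float = TRIM_LO, hi: float = TRIM_HI
) -> Tuple[pd.DataFrame, int, float]:
    """Eliminate implausibly fast and slow responses.

    Non-reference trials are kept when their RT lies inside ``[lo, hi]``
    (inclusive); trials with missing RTs are eliminated as well. Reference
    rows pass through untouched (they carry no RT and are excluded from the
    elimination statistics); practice flags are not consulted here.

    Returns ``(kept, n_eliminated, fraction_eliminated)`` where the fraction
    is relative to the number of non-reference trials.
    """
    if not lo < hi:
        raise ConfigurationError(f"invalid trimming window [{lo}, {hi}]")
    is_ref = trials["is_reference"].astype(bool)
    in_window = trials["rt_s"].ge(lo) & trials["rt_s"].le(hi)
    keep = is_ref | in_window
    n_nonref = int((~is_ref).sum())
    n_elim = int((~keep).sum())
    kept = trials[keep].reset_index(drop=True)
    frac = n_elim / n_nonref if n_nonref else 0.0
    return kept, n_elim, frac
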