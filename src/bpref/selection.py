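"""Triplicate blood-pressure value selection.

Each child is measured three times.  The recorded BP is the average of
two consecutive measurements that differ by less than 5 mmHg, preferring
the second–third pair; when the second measurement is missing, the
first–third average is adopted under the same <5 mmHg rule.  Children
whose readings never satisfy the rule are "unstable"; children crying,
sleeping, feverish or unable to hold a measurement posture are excluded
regardless of readings.  SBP and DBP channels are selected independently,
so a child can contribute to one analysis and not the other; a DBP of
0 mmHg (inaudible fifth Korotkoff sound) invalidates the DBP channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementTriplet",
    "SelectionResult",
    "select_bp_value",
    "select_record",
    "select_dataframe",
    "STABLE",
    "DIFF_LIMIT_MMHG",
]

DIFF_LIMIT_MMHG = 5.0  # strict: a difference of exactly 5 rejects

STABLE = "stable"
CONDITION_FLAGS = (STABLE, "crying", "sleeping", "fever", "unstable_posture")
POSTURES = ("sitting", "supine", "other")

ACCEPTED = "accepted"
REJECTED_UNSTABLE = "rejected_unstable"
REJECTED_MISSING = "rejected_missing"
REJECTED_DBP_ZERO = "rejected_dbp_zero"


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the triplicate rule on one channel.

    ``value`` is present iff ``status == 'accepted'`` and is the
    arithmetic mean of the pair identified by ``pair_used`` (1-based
    reading indices), kept at one decimal place of precision.
    """

    value: Optional[float]
    status: str
    pair_used: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class MeasurementTriplet:
    """Three ordered (SBP, DBP) readings plus measurement-context flags.

    ``sbp`` / ``dbp``: length-3 sequences, ``None`` = missing.  Present
    readings must be positive (DBP may be 0, recording an inaudible
    endpoint).  SBP must exceed DBP whenever both are present and DBP>0.
    """

    sbp: tuple
    dbp: tuple
    posture: str = "sitting"
    condition_flag: str = STABLE

    def __post_init__(self):
        if len(self.sbp) != 3 or len(self.dbp) != 3:
            raise ValueError("triplet must have exactly 3 readings per channel")
        if self.condition_flag not in CONDITION_FLAGS:
            raise ValueError(f"unknown condition flag {self.condition_flag!r}")
        if self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")
        for s in self.sbp:
            if s is not None and s <= 0:
                raise ValueError("SBP readings must be positive")
        for d in self.dbp:
            if d is not None and d < 0:
                raise ValueError("DBP readings must be non-negative")
        for s, d in zip(self.sbp, self.dbp):
            if s is not None and d is not None and d > 0 and s <= d:
                raise ValueError("SBP must exceed DBP within a reading")


def select_bp_value(readings: Sequence[Optional[float]]) -> SelectionResult:
    """Apply the consecutive-pair selection rule to one channel.

    Cascade: (m2, m3) within <5 mmHg → their mean; else (m1, m2) within
    <5 mmHg → their mean; else, when m2 is missing, (m1, m3) within
    <5 mmHg → their mean; else rejected (``rejected_missing`` when two
    or more readings are absent, ``rejected_unstable`` otherwise).
    """
    if len(readings) != 3:
        raise ValueError("exactly 3 reading slots required")
    m = [None if r is None or (isinstance(r, float) and np.isnan(r)) else float(r) for r in readings]
    for r in m:
        if r is not None and r <= 0:
            raise ValueError("readings must be positive")
    m1, m2, m3 = m
    if m2 is not None and m3 is not None and abs(m2 - m3) < DIFF_LIMIT_MMHG:
        return SelectionResult(round((m2 + m3) / 2.0, 1), ACCEPTED, (2, 3))
    if m1 is not None and m2 is not None and abs(m1 - m2) < DIFF_LIMIT_MMHG:
        return SelectionResult(round((m1 + m2) / 2.0, 1), ACCEPTED, (1, 2))
    if m2 is None and m1 is not None and m3 is not None and abs(m1 - m3) < DIFF_LIMIT_MMHG:
        return SelectionResult(round((m1 + m3) / 2.0, 1), ACCEPTED, (1, 3))
    if sum(r is None for r in m) >= 2:
        return SelectionResult(None, REJECTED_MISSING)
    return SelectionResult(None, REJECTED_UNSTABLE)


def select_record(triplet: MeasurementTriplet) -> tuple[SelectionResult, SelectionResult]:
    """Select SBP and DBP values for one child, channel by channel.

    An unstable condition flag rejects both channels outright.  On the
    DBP channel, a 0 mmHg reading in the adopted pair (or a pair made
    eligible only by 0 readings) yields ``rejected_dbp_zero``.
    """
    if triplet.condition_flag != STABLE:
        return (
            SelectionResult(None, REJECTED_UNSTABLE),
            SelectionResult(None, REJECTED_UNSTABLE),
        )
    sbp = select_bp_value(triplet.sbp)
    # DBP 0 readings are placeholders, not measurements: run the cascade on
    # positive readings only, then flag the channel if any 0 was recorded in
    # a slot the cascade would have used.
    dbp_in = [None if (d is not None and d == 0) else d for d in triplet.dbp]
    dbp = select_bp_value(dbp_in)
    if any(d is not None and d == 0 for d in triplet.dbp):
        dbp = SelectionResult(None, REJECTED_DBP_ZERO)
    return sbp, dbp


def select_dataframe(df: pd.DataFrame) -> pd.DataFrame:
    """Run the selection rule over a cohort table.

    Expects columns ``sbp1..sbp3``, ``dbp1..dbp3`` (NaN = missing) and
    ``condition_flag``; returns a copy with ``sbp_selected``,
    ``dbp_selected``, ``sbp_status``, ``dbp_status`` appended.
    """
    out = df.copy()
    sel = {k: [] for k in ("sbp_selected", "dbp_selected", "sbp_status", "dbp_status")}
    for row in df.itertuples(index=False):
        trip = MeasurementTriplet(
            sbp=tuple(_opt(getattr(row, f"sbp{i}")) for i in (1, 2, 3)),
            dbp=tuple(_opt(getattr(row, f"dbp{i}")) for i in (1, 2, 3)),
            posture=getattr(row, "posture", "sitting"),
            condition_flag=getattr(row, "condition_flag", STABLE),
        )
        s, d = select_record(trip)
        sel["sbp_selected"].append(s.value if s.value is not None else np.nan)
        sel["dbp_selected"].append(d.value if d.value is not None else np.nan)
        sel["sbp_status"].append(s.status)
        sel["dbp_status"].append(d.status)
    for k, v in sel.items():
        out[k] = v
    return out


def _opt(x):
    if x is None:
        return None
    try:
        if np.isnan(x):
            return None
    except TypeError:
        pass
    return float(x)
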