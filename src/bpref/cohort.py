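"""Exclusion cascade and participant-flow accounting.

Six exclusion criteria are applied in a fixed order, separately for the
SBP and DBP channels (a child can survive in one channel only):

1. chronic disease;
2.+3. two or more missing BP values / DBP of 0 mmHg / unstable posture
   or condition (crying, sleeping, fever) — one grouped flow box, with
   sub-reasons logged;
4. unstable BP values (no consecutive pair within <5 mmHg);
5. missing covariates or height more than 5 SD from the growth standard;
6. age under 24 months.

Every record lands in exactly one bucket per channel (the first
applicable), so bucket counts sum to the channel total — the same
book-keeping a study flowchart reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import OUTLIER_SD, GrowthStandard
from .selection import (
    REJECTED_DBP_ZERO,
    REJECTED_MISSING,
    REJECTED_UNSTABLE,
    STABLE,
    select_dataframe,
)

__all__ = ["FlowAccounting", "apply_exclusions", "cohort_summary", "MIN_AGE_MONTHS"]

MIN_AGE_MONTHS = 24

BUCKETS = (
    "excluded_chronic",
    "excluded_missing_or_condition",
    "excluded_unstable_bp",
    "excluded_covariates_or_height_outlier",
    "excluded_underage",
    "analyzed",
)

#: covariates whose absence triggers exclusion (5)
REQUIRED_COVARIATES = ("sex", "age_months", "height_cm", "weight_kg", "season")


@dataclass
class FlowAccounting:
    """Per-channel exclusion counts mirroring a participant flowchart."""

    total_in: int
    counts: dict = field(default_factory=dict)  # channel -> bucket -> n
    sub_reasons: dict = field(default_factory=dict)  # channel -> reason -> n

    def check_conservation(self) -> bool:
        return all(
            sum(b.values()) == self.total_in for b in self.counts.values()
        )

    def to_dict(self) -> dict:
        return {
            "total_in": self.total_in,
            "channels": self.counts,
            "sub_reasons": self.sub_reasons,
        }

    def to_text(self) -> str:
        lines = [f"records in: {self.total_in}"]
        for ch, buckets in self.counts.items():
            lines.append(f"[{ch.upper()}]")
            for b in BUCKETS:
                lines.append(f"  {b}: {buckets.get(b, 0)}")
        return "\n".join(lines)


def _bucket_for(row, status_col, standard: GrowthStandard):
    """First applicable exclusion bucket for one record on one channel."""
    if bool(row.get("chronic_disease", False)):
        return "excluded_chronic", "chronic_disease"
    status = row[status_col]
    if status == REJECTED_MISSING:
        return "excluded_missing_or_condition", "missing_bp"
    if status == REJECTED_DBP_ZERO:
        return "excluded_missing_or_condition", "dbp_zero"
    if status == REJECTED_UNSTABLE and row.get("condition_flag", STABLE) != STABLE:
        return "excluded_missing_or_condition", f"condition_{row['condition_flag']}"
    if status == REJECTED_UNSTABLE:
        return "excluded_unstable_bp", "bp_instability"
    # status == accepted from here on
    for cov in REQUIRED_COVARIATES:
        v = row.get(cov, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return "excluded_covariates_or_height_outlier", f"missing_{cov}"
    zht = row.get("zht", np.nan)
    if not np.isfinite(zht) or abs(zht) > OUTLIER_SD:
        return "excluded_covariates_or_height_outlier", "height_outlier"
    if int(row["age_months"]) < MIN_AGE_MONTHS:
        return "excluded_underage", "underage"
    return "analyzed", None


def apply_exclusions(
    records: pd.DataFrame, standard: GrowthStandard
) -> tuple[pd.DataFrame, pd.DataFrame, FlowAccounting]:
    """Run selection, Z-scoring and the exclusion cascade over a cohort.

    Parameters
    ----------
    records : pandas.DataFrame
        Cohort table with the raw-measurement schema (``sbp1..3``,
        ``dbp1..3``, covariates, flags).
    standard : GrowthStandard
        Growth standard for height Z-scoring.

    Returns
    -------
    (sbp_set, dbp_set, flow)
        Analyzed DataFrames per channel — carrying ``zht`` and the
        selected BP in a ``bp`` column — and the flow accounting.
    """
    df = select_dataframe(records) if "sbp_status" not in records.columns else records.copy()

    # height Z-score where computable; malformed rows fall through to (5)
    zht = np.full(len(df), np.nan)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            sex = getattr(row, "sex")
            age = getattr(row, "age_months")
            h = getattr(row, "height_cm")
            if pd.isna(h) or pd.isna(age) or not isinstance(sex, str):
                continue
            zht[i] = standard.zscore(float(h), sex, float(age))
        except (ValueError, KeyError):
            continue
    df["zht"] = zht

    flow = FlowAccounting(total_in=len(df))
    analyzed = {}
    for channel, status_col, value_col in (
        ("sbp", "sbp_status", "sbp_selected"),
        ("dbp", "dbp_status", "dbp_selected"),
    ):
        counts = {b: 0 for b in BUCKETS}
        reasons: dict[str, int] = {}
        keep = np.zeros(len(df), dtype=bool)
        for i, (_, row) in enumerate(df.iterrows()):
            bucket, reason = _bucket_for(row, status_col, standard)
            counts[bucket] += 1
            if reason is not None:
                reasons[reason] = reasons.get(reason, 0) + 1
            keep[i] = bucket == "analyzed"
        flow.counts[channel] = counts
        flow.sub_reasons[channel] = reasons
        sub = df.loc[keep].copy()
        sub["bp"] = sub[value_col]
        analyzed[channel] = sub

    assert flow.check_conservation()
    return analyzed["sbp"], analyzed["dbp"], flow


def cohort_summary(sbp_set: pd.DataFrame, dbp_set: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Descriptive summary of the analyzed sets (Table-1 style).

    Reports per stratum (overall, or by ``by`` label): n children, %
    male, mean (sample SD) of height, weight, selected SBP and DBP, and
    the per-channel available n.  All children appearing in either
    channel contribute to the anthropometry; BP statistics use the
    respective channel's analyzed set.
    """
    union = pd.concat([sbp_set, dbp_set]).drop_duplicates(subset="child_id")
    if union.empty:
        return pd.DataFrame({"stratum": ["(empty)"], "n": [0]})

    def _one(label, u, s, d):
        n = len(u)
        row = {
            "stratum": label,
            "n": n,
            "pct_male": 100.0 * (u["sex"] == "boy").mean() if n else np.nan,
            "height_mean": u["height_cm"].mean(),
            "height_sd": u["height_cm"].std(ddof=1),
            "weight_mean": u["weight_kg"].mean(),
            "weight_sd": u["weight_kg"].std(ddof=1),
            "sbp_n": len(s),
            "sbp_mean": s["bp"].mean() if len(s) else np.nan,
            "sbp_sd": s["bp"].std(ddof=1) if len(s) else np.nan,
            "dbp_n": len(d),
            "dbp_mean": d["bp"].mean() if len(d) else np.nan,
            "dbp_sd": d["bp"].std(ddof=1) if len(d) else np.nan,
        }
        return row

    rows = [_one("total", union, sbp_set, dbp_set)]
    if by is not None and by in union.columns:
        for label, u in union.groupby(by):
            s = sbp_set[sbp_set[by] == label]
            d = dbp_set[dbp_set[by] == label]
            rows.append(_one(str(label), u, s, d))
    return pd.DataFrame(rows)
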