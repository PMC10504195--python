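"""Height Z-scores against a pluggable LMS growth standard.

A :class:`GrowthStandard` is an (sex, age-in-months) lookup of the L, M, S
parameters of height.  A child's height Z-score (Zht) is the BCCG z-score
of their height against the row (or age-interpolated row) matching their
sex and age; |Zht| > 5 flags an implausible height that the exclusion
cascade removes.

The national growth-standard tables the reference values were built
against are not redistributable, so :func:`synthetic_growth_standard`
ships a synthetic stand-in with realistic level and spread for ages
18–42 months.  It is NOT a national standard and must not be used
clinically; any standard with the same CSV schema can be plugged in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bccg import bccg_centile, bccg_zscore

__all__ = [
    "GrowthStandard",
    "ZScoreResult",
    "height_zscore",
    "zht_from_height_percentile",
    "synthetic_growth_standard",
]

OUTLIER_SD = 5.0  # |Zht| beyond this is treated as a measurement error

_SEXES = ("boy", "girl")


@dataclass(frozen=True)
class ZScoreResult:
    zht: float
    outlier: bool


class GrowthStandard:
    """Sex- and age-specific L/M/S lookup for height.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``sex`` (boy/girl), ``age_months`` (int), ``L``, ``M``
        (cm, > 0), ``S`` (> 0).  (sex, age_months) keys must be unique.
        A mean/SD standard is the ``L = 1`` special case with
        ``M = mean`` and ``S = SD/mean``.
    """

    REQUIRED = ("sex", "age_months", "L", "M", "S")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"growth standard missing columns: {missing}")
        t = table[list(self.REQUIRED)].copy()
        t["sex"] = t["sex"].astype(str)
        bad_sex = set(t["sex"]) - set(_SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex values in growth standard: {bad_sex}")
        if (t["M"] <= 0).any() or (t["S"] <= 0).any():
            raise ValueError("growth standard requires M > 0 and S > 0")
        if t.duplicated(["sex", "age_months"]).any():
            raise ValueError("duplicate (sex, age_months) rows in growth standard")
        t = t.sort_values(["sex", "age_months"]).reset_index(drop=True)
        self.table = t
        self._by_sex = {
            s: g.set_index("age_months")[["L", "M", "S"]]
            for s, g in t.groupby("sex")
        }

    @classmethod
    def from_csv(cls, path) -> "GrowthStandard":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def age_range(self, sex: str) -> tuple[int, int]:
        idx = self._by_sex[sex].index
        return int(idx.min()), int(idx.max())

    def lms(self, sex: str, age_months) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """L, M, S at ``age_months`` (linear interpolation between ages)."""
        if sex not in self._by_sex:
            raise ValueError(f"sex {sex!r} not in growth standard")
        g = self._by_sex[sex]
        age = np.asarray(age_months, dtype=float)
        lo, hi = g.index.min(), g.index.max()
        if np.any(age < lo) or np.any(age > hi):
            raise ValueError(
                f"age {age_months} outside standard coverage [{lo}, {hi}] for {sex}"
            )
        ages = g.index.to_numpy(dtype=float)
        out = tuple(
            np.interp(age, ages, g[c].to_numpy(dtype=float)) for c in ("L", "M", "S")
        )
        return out

    def zscore(self, height_cm, sex: str, age_months) -> np.ndarray:
        L, M, S = self.lms(sex, age_months)
        return bccg_zscore(height_cm, L, M, S)

    def height_at(self, p: float, sex: str, age_months) -> np.ndarray:
        """Height at percentile ``p`` of the standard (inverse of zscore)."""
        L, M, S = self.lms(sex, age_months)
        return bccg_centile(p, L, M, S)


def height_zscore(height_cm, sex, age_months, standard: GrowthStandard) -> ZScoreResult:
    """Height Z-score of one child, with the ±5 SD outlier flag."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    z = float(standard.zscore(height_cm, sex, age_months))
    return ZScoreResult(zht=z, outlier=abs(z) > OUTLIER_SD)


def zht_from_height_percentile(p):
    """Height Z-score corresponding to a height percentile: the standard
    normal quantile of ``p`` (p in (0, 1))."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("percentile must lie in (0, 1)")
    out = norm.ppf(p)
    return out if out.ndim else float(out)


def synthetic_growth_standard(
    age_min: int = 18, age_max: int = 42
) -> GrowthStandard:
    """Synthetic L/M/S height standard for toddlers (stand-in, not national data).

    Median height at 24 months is 83.3 cm for boys and 82.3 cm for
    girls, growing 0.75 cm/month with a mild age taper; S is 0.034
    (≈2.85 cm SD at this age); L is 1 (heights are close to normal at a
    fixed age).  The level is chosen so the default simulated cohort
    (height ~ N(84.0, 2.9) cm, ages 24–27 months) has height Z-scores
    centred at 0 — internal consistency with the generator, NOT an
    estimate of any national chart.
    """
    rows = []
    for sex, m24 in (("boy", 83.3), ("girl", 82.3)):
        for age in range(age_min, age_max + 1):
            d = age - 24
            m = m24 + 0.75 * d - 0.004 * d * d  # gentle deceleration
            rows.append({"sex": sex, "age_months": age, "L": 1.0, "M": round(m, 2), "S": 0.034})
    return GrowthStandard(pd.DataFrame(rows))
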