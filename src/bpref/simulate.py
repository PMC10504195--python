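"""Synthetic cohort generation calibrated to published reference values.

The cohort the reference values were built from is access-restricted, so
this module generates cohorts with the same statistical structure: a
sex- and height-dependent blood-pressure distribution, triplicate
readings with within-child noise, and the missingness / instability /
condition categories the exclusion cascade consumes.

The generating BP distributions ("truth surfaces") are Box–Cox–Cole–
Green families whose L/M/S knots over height Z-score are recovered by
quantile matching from the published 7 (height percentile) × 4 (BP
percentile) reference grid — the only principled ground truth available
at desk scale.  L/M/S vary smoothly (low-order polynomials) over the
knot range; beyond the outermost knots (height percentiles 5 and 95)
they are held flat, since the table carries no information there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from functools import lru_cache
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .bccg import bccg_centile, calibrate_from_quantiles
from .growth import GrowthStandard, synthetic_growth_standard

__all__ = [
    "TruthSurface",
    "SimulationConfig",
    "calibrate_bccg_from_quantiles",
    "table2_presets",
    "reference_grid",
    "generate_cohort",
    "fig1_like_config",
    "DEFAULT_SEED",
    "BP_PERCENTILES",
    "HEIGHT_PERCENTILES",
]

#: documented default seed for reproducible cohorts
DEFAULT_SEED = 20150401

BP_PERCENTILES = (0.50, 0.90, 0.95, 0.99)
HEIGHT_PERCENTILES = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)

# Published reference grid (integer mmHg), rows = BP percentiles
# (50/90/95/99), columns = height percentiles (5/10/25/50/75/90/95).
_REFERENCE_GRID = {
    ("boy", "sbp"): [
        [90, 90, 91, 91, 92, 92, 92],
        [101, 101, 102, 102, 103, 103, 104],
        [105, 105, 105, 106, 106, 107, 107],
        [111, 111, 112, 112, 113, 113, 114],
    ],
    ("boy", "dbp"): [
        [51, 51, 51, 52, 52, 53, 53],
        [61, 61, 62, 62, 63, 63, 63],
        [64, 64, 65, 65, 66, 66, 66],
        [70, 70, 70, 71, 71, 72, 72],
    ],
    ("girl", "sbp"): [
        [89, 89, 90, 90, 91, 91, 92],
        [99, 99, 100, 101, 101, 102, 102],
        [102, 102, 103, 103, 104, 105, 105],
        [107, 108, 108, 109, 110, 110, 111],
    ],
    ("girl", "dbp"): [
        [51, 51, 51, 52, 52, 53, 53],
        [61, 61, 62, 62, 63, 63, 64],
        [64, 64, 65, 65, 66, 66, 67],
        [69, 70, 70, 71, 72, 72, 73],
    ],
}

#: re-export of the calibration solver under its pipeline-facing name
calibrate_bccg_from_quantiles = calibrate_from_quantiles


def reference_grid(sex: str, outcome: str) -> pd.DataFrame:
    """The published reference grid as a DataFrame (rows: BP percentile,
    columns: height percentile), integer mmHg."""
    grid = _REFERENCE_GRID[(sex, outcome)]
    return pd.DataFrame(
        grid,
        index=pd.Index([int(p * 100) for p in BP_PERCENTILES], name="bp_percentile"),
        columns=pd.Index(
            [int(p * 100) for p in HEIGHT_PERCENTILES], name="height_percentile"
        ),
    )


@dataclass(frozen=True)
class TruthSurface:
    """Generating BCCG parameter curves over height Z-score."""

    sex: str
    outcome: str
    L_fn: Callable[[np.ndarray], np.ndarray]
    M_fn: Callable[[np.ndarray], np.ndarray]
    S_fn: Callable[[np.ndarray], np.ndarray]

    def lms(self, zht):
        zht = np.asarray(zht, dtype=float)
        return self.L_fn(zht), self.M_fn(zht), self.S_fn(zht)

    def centile(self, p, zht):
        """True centile of the surface at probability p and height Z-score zht."""
        L, M, S = self.lms(zht)
        return bccg_centile(p, L, M, S)

    def sample(self, zht, u):
        """BP values for standard-normal draws ``u`` at height Z-scores ``zht``."""
        L, M, S = self.lms(zht)
        base = 1.0 + L * S * np.asarray(u, dtype=float)
        small = np.abs(L) < 1e-8
        Lsafe = np.where(small, 1.0, L)
        with np.errstate(invalid="ignore"):
            y = np.where(
                small,
                M * np.exp(S * u),
                M * np.power(np.where(base > 0, base, np.nan), 1.0 / Lsafe),
            )
        return y


def _surface_from_grid(sex: str, outcome: str) -> TruthSurface:
    """Smoothest BCCG surface reproducing the printed grid within rounding.

    The published table was produced by a smooth LMS fit and then
    rounded to integers; calibrating each height column independently
    treats that rounding noise as real structure (the implied S jumps by
    ±0.04 between adjacent columns, which no physiology supports, and a
    downstream smooth fit then cannot recover the surface).  Instead the
    surface is parameterized in the same class the fit searches —
    M quadratic, L linear, S quadratic in Zht — and least-squares
    matched to all 28 cells; every residual must stay within the 0.5
    mmHg rounding half-width of the printed integers.
    """
    from scipy.optimize import least_squares

    knots = norm.ppf(HEIGHT_PERCENTILES)
    grid = np.asarray(_REFERENCE_GRID[(sex, outcome)], dtype=float)
    zp = norm.ppf(BP_PERCENTILES)

    def cells(par):
        aM, bM, cM, aL, bL, aS, bS, cS = par
        out = np.empty((len(zp), len(knots)))
        for j, z in enumerate(knots):
            M = aM + bM * z + cM * z * z
            L = aL + bL * z
            S = aS + bS * z + cS * z * z
            base = 1.0 + L * S * zp
            if np.any(base <= 0) or S <= 0 or M <= 0:
                return None
            out[:, j] = (
                M * np.power(base, 1.0 / L) if abs(L) > 1e-8 else M * np.exp(S * zp)
            )
        return out

    def resid(par):
        c = cells(par)
        return np.full(grid.size, 1e3) if c is None else (c - grid).ravel()

    x0 = [
        grid[0, 3],
        (grid[0, -1] - grid[0, 0]) / (knots[-1] - knots[0]),
        0.0,
        0.5,
        0.0,
        0.12,
        0.0,
        0.0,
    ]
    sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15)
    c = cells(sol.x)
    err = np.abs(c - grid)
    if c is None or err.max() > 0.5:
        i, j = np.unravel_index(np.argmax(err), err.shape)
        raise RuntimeError(
            f"preset calibration failed for {sex}/{outcome}: cell at height "
            f"percentile {HEIGHT_PERCENTILES[j]:.2f}, BP percentile "
            f"{BP_PERCENTILES[i]:.2f} misses by {err.max():.3f} mmHg"
        )
    aM, bM, cM, aL, bL, aS, bS, cS = sol.x
    lo, hi = knots[0], knots[-1]

    def poly(a, b, c_):
        def f(z):
            z = np.clip(np.asarray(z, dtype=float), lo, hi)  # flat beyond knots
            return a + b * z + c_ * z * z

        return f

    return TruthSurface(
        sex=sex,
        outcome=outcome,
        L_fn=poly(aL, bL, 0.0),
        M_fn=poly(aM, bM, cM),
        S_fn=poly(aS, bS, cS),
    )


@lru_cache(maxsize=1)
def _presets() -> dict:
    out = {}
    for sex in ("boy", "girl"):
        for outcome in ("sbp", "dbp"):
            name = f"jecs-{sex}s-{outcome}"
            out[name] = _surface_from_grid(sex, outcome)
    return out


def table2_presets() -> dict:
    """Truth-surface presets calibrated from the published reference grid.

    Keys: ``jecs-boys-sbp``, ``jecs-boys-dbp``, ``jecs-girls-sbp``,
    ``jecs-girls-dbp``.
    """
    return dict(_presets())


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings.

    Proportions are probabilities of mutually exclusive planted
    categories (their sum must be <= 1); ``missing_second_rate`` plants a
    missing second reading (exercising the selection fallback, not an
    exclusion).  With all nuisance rates at their 0 defaults the
    generator emits a clean cohort whose only rejections come from
    reading noise hitting the <5 mmHg stability rule.
    """

    n_children: int = 3361
    pct_boys: float = 0.497
    seed: int = DEFAULT_SEED
    truth: Optional[dict] = None  # (sex, outcome) -> TruthSurface; None = presets
    height_mean_cm: float = 84.0
    height_sd_cm: float = 2.9
    age_months_range: tuple = (24, 27)
    missing_second_rate: float = 0.0
    missing_two_rate: float = 0.0
    unstable_rate: float = 0.0
    crying_rate: float = 0.0
    chronic_rate: float = 0.0
    dbp_zero_rate: float = 0.0
    underage_rate: float = 0.0
    height_outlier_rate: float = 0.0
    within_child_noise_sd: float = 1.5
    rounding_step_mmhg: float = 2.0
    bp_correlation: float = 0.5

    _RATES = (
        "missing_second_rate",
        "missing_two_rate",
        "unstable_rate",
        "crying_rate",
        "chronic_rate",
        "dbp_zero_rate",
        "underage_rate",
        "height_outlier_rate",
    )

    def __post_init__(self):
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if not 0.0 <= self.pct_boys <= 1.0:
            raise ValueError("pct_boys must lie in [0, 1]")
        rates = [getattr(self, r) for r in self._RATES]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if sum(rates) > 1.0 + 1e-12:
            raise ValueError("planted-category rates must sum to <= 1")
        if self.within_child_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.age_months_range[0] > self.age_months_range[1]:
            raise ValueError("age_months_range must be (lo, hi) with lo <= hi")
        if not -0.999 < self.bp_correlation < 0.999:
            raise ValueError("bp_correlation must lie in (-1, 1)")

    def resolve_truth(self) -> dict:
        if self.truth is not None:
            return self.truth
        p = table2_presets()
        return {
            ("boy", "sbp"): p["jecs-boys-sbp"],
            ("boy", "dbp"): p["jecs-boys-dbp"],
            ("girl", "sbp"): p["jecs-girls-sbp"],
            ("girl", "dbp"): p["jecs-girls-dbp"],
        }

    # ---- serialization (truth surfaces travel by preset, not by value) ----

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "truth"
        }
        d["age_months_range"] = list(self.age_months_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "age_months_range" in d:
            d["age_months_range"] = tuple(d["age_months_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fig1_like_config(n_children: int = 4988, seed: int = DEFAULT_SEED) -> SimulationConfig:
    """Config whose planted-category rates emulate the published
    participant-flow proportions (chronic ~0.6%, missing/condition ~25%,
    planted instability ~7%, underage ~5%)."""
    return SimulationConfig(
        n_children=n_children,
        seed=seed,
        chronic_rate=0.006,
        missing_two_rate=0.10,
        crying_rate=0.13,
        dbp_zero_rate=0.02,
        unstable_rate=0.07,
        underage_rate=0.048,
        height_outlier_rate=0.002,
        missing_second_rate=0.02,
    )


_CATEGORIES = (
    "none",
    "chronic",
    "missing_two",
    "crying",
    "dbp_zero",
    "unstable",
    "underage",
    "height_outlier",
    "missing_second",
)


def generate_cohort(
    config: SimulationConfig,
    standard: GrowthStandard | None = None,
    return_truth: bool = False,
):
    """Generate a synthetic cohort as a DataFrame in the cohort-CSV schema.

    Columns: ``child_id, sex, age_months, height_cm, weight_kg, season,
    chronic_disease, posture, condition_flag, sbp1..3, dbp1..3`` (NaN =
    missing; written as empty strings by :func:`write_cohort_csv`).

    With ``return_truth=True`` also returns a bookkeeping DataFrame with
    each child's planted category, height Z-score and latent true BP —
    the oracle for flow-accounting and recovery tests.

    Deterministic: identical config (including seed) gives identical
    output.
    """
    if standard is None:
        standard = synthetic_growth_standard()
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    truth = config.resolve_truth()

    # sex: target the proportion, not an exact count per draw
    n_boys = round(n * config.pct_boys)  # banker's rounding, documented
    sex = np.array(["boy"] * n_boys + ["girl"] * (n - n_boys))
    rng.shuffle(sex)

    # planted nuisance categories, mutually exclusive
    probs = [
        1.0
        - sum(
            getattr(config, r)
            for r in (
                "chronic_rate",
                "missing_two_rate",
                "crying_rate",
                "dbp_zero_rate",
                "unstable_rate",
                "underage_rate",
                "height_outlier_rate",
                "missing_second_rate",
            )
        ),
        config.chronic_rate,
        config.missing_two_rate,
        config.crying_rate,
        config.dbp_zero_rate,
        config.unstable_rate,
        config.underage_rate,
        config.height_outlier_rate,
        config.missing_second_rate,
    ]
    category = rng.choice(_CATEGORIES, size=n, p=probs)

    lo, hi = config.age_months_range
    age = rng.integers(lo, hi + 1, size=n)
    age[category == "underage"] = rng.integers(22, 24, size=(category == "underage").sum())

    # heights: normal, truncated at +/-5 SD of the standard; planted
    # outliers overwrite with |Zht| in (5.2, 6.5)
    height = rng.normal(config.height_mean_cm, config.height_sd_cm, size=n)
    Lh = np.empty(n)
    Mh = np.empty(n)
    Sh = np.empty(n)
    for s in ("boy", "girl"):
        m = sex == s
        Lh[m], Mh[m], Sh[m] = standard.lms(s, age[m])
    for _ in range(100):
        zh = _bccg_z(height, Lh, Mh, Sh)
        bad = (np.abs(zh) > 5.0) & (category != "height_outlier")
        if not bad.any():
            break
        height[bad] = rng.normal(config.height_mean_cm, config.height_sd_cm, size=bad.sum())
    is_out = category == "height_outlier"
    if is_out.any():
        z_out = rng.uniform(5.2, 6.5, size=is_out.sum()) * rng.choice([-1, 1], size=is_out.sum())
        base = 1.0 + Lh[is_out] * Sh[is_out] * z_out
        height[is_out] = Mh[is_out] * np.power(np.maximum(base, 1e-6), 1.0 / Lh[is_out])
    height = np.round(height, 1)
    zht = _bccg_z(height, Lh, Mh, Sh)

    weight = np.round(
        np.maximum(11.5 + 0.25 * (height - 84.0) + rng.normal(0, 1.1, size=n), 5.0), 1
    )

    # latent true BP: correlated SBP/DBP draws from the truth surfaces
    rho = config.bp_correlation
    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    u_s = u1
    u_d = rho * u1 + np.sqrt(1 - rho * rho) * u2
    true_sbp = np.empty(n)
    true_dbp = np.empty(n)
    for s in ("boy", "girl"):
        m = sex == s
        true_sbp[m] = truth[(s, "sbp")].sample(zht[m], u_s[m])
        true_dbp[m] = truth[(s, "dbp")].sample(zht[m], u_d[m])
    # out-of-support draws or inverted pairs are re-drawn (essentially never
    # triggers at realistic S)
    for _ in range(100):
        bad = ~np.isfinite(true_sbp) | ~np.isfinite(true_dbp) | (true_sbp <= true_dbp + 5)
        if not bad.any():
            break
        k = int(bad.sum())
        v1 = rng.standard_normal(k)
        v2 = rng.standard_normal(k)
        for s in ("boy", "girl"):
            m = bad & (sex == s)
            mm = m[bad]
            if m.any():
                true_sbp[m] = truth[(s, "sbp")].sample(zht[m], v1[mm])
                true_dbp[m] = truth[(s, "dbp")].sample(zht[m], (rho * v1 + np.sqrt(1 - rho**2) * v2)[mm])

    step = config.rounding_step_mmhg
    noise = config.within_child_noise_sd

    def readings(true):
        r = true[:, None] + rng.normal(0.0, noise, size=(n, 3))
        if step > 0:
            r = np.round(r / step) * step
        return np.maximum(r, step if step > 0 else 1.0)

    sbp_r = readings(true_sbp)
    dbp_r = readings(true_dbp)

    # planted instability: spread readings so no consecutive pair is <5 apart
    unst = category == "unstable"
    if unst.any():
        k = unst.sum()
        offs = np.stack(
            [np.full(k, -6.0), np.zeros(k), rng.choice([6.0, 8.0], size=k)], axis=1
        )
        sbp_r[unst] = np.round((true_sbp[unst, None] + offs) / step) * step if step > 0 else true_sbp[unst, None] + offs
        dbp_r[unst] = np.round((true_dbp[unst, None] + offs) / step) * step if step > 0 else true_dbp[unst, None] + offs

    miss2 = (category == "missing_second") | (category == "missing_two")
    sbp_r[miss2, 1] = np.nan
    dbp_r[miss2, 1] = np.nan
    two = category == "missing_two"
    sbp_r[two, 2] = np.nan
    dbp_r[two, 2] = np.nan
    dz = category == "dbp_zero"
    dbp_r[dz, :] = 0.0

    condition = np.full(n, "stable", dtype=object)
    cry = category == "crying"
    condition[cry] = rng.choice(["crying", "sleeping", "fever"], size=cry.sum(), p=[0.6, 0.3, 0.1])
    # the "unstable" category plants unstable readings, not posture
    posture = np.where(rng.random(n) < 0.0024, "supine", "sitting")

    season = rng.choice(
        ["spring", "summer", "autumn", "winter"], size=n, p=[0.27, 0.27, 0.27, 0.19]
    )

    df = pd.DataFrame(
        {
            "child_id": [f"C{i:05d}" for i in range(n)],
            "sex": sex,
            "age_months": age,
            "height_cm": height,
            "weight_kg": weight,
            "season": season,
            "chronic_disease": category == "chronic",
            "posture": posture,
            "condition_flag": condition,
            "sbp1": sbp_r[:, 0],
            "sbp2": sbp_r[:, 1],
            "sbp3": sbp_r[:, 2],
            "dbp1": dbp_r[:, 0],
            "dbp2": dbp_r[:, 1],
            "dbp3": dbp_r[:, 2],
        }
    )
    if not return_truth:
        return df
    truth_df = pd.DataFrame(
        {
            "child_id": df["child_id"],
            "planted_category": category,
            "zht": zht,
            "true_sbp": true_sbp,
            "true_dbp": true_dbp,
        }
    )
    return df, truth_df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort in the canonical CSV schema (empty string = missing)."""
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["chronic_disease"] = df["chronic_disease"].astype(bool)
    return df


def _bccg_z(y, L, M, S):
    logr = np.log(y) - np.log(M)
    small = np.abs(L) < 1e-8
    Lsafe = np.where(small, 1.0, L)
    return np.where(small, logr / S, (np.exp(Lsafe * logr) - 1.0) / (Lsafe * S))
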