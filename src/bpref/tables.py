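"""Reference-table construction: BP percentiles × height percentiles.

The clinical deliverable is a grid of integer BP values at BP percentiles
{50, 90, 95, 99} and height percentiles {5, 10, 25, 50, 75, 90, 95},
per sex and outcome.  Height percentiles are converted to height
Z-scores via the standard normal quantile; each cell is the fitted
model's centile there, rounded half-up to integer mmHg (the published
table prints integers; the rounding rule is this package's choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import zht_from_height_percentile
from .simulate import BP_PERCENTILES, HEIGHT_PERCENTILES

__all__ = ["ReferenceTable", "build_reference_table", "compare_tables", "round_half_up"]


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with halves away from zero (mmHg grid)."""
    x = np.asarray(x, dtype=float)
    out = np.floor(x + 0.5)
    return out.astype(int) if out.ndim else int(out)


@dataclass
class ReferenceTable:
    """Height-percentile × BP-percentile grid of integer mmHg values."""

    sex: str
    outcome: str
    model_kind: str  # "lms" | "polynomial"
    grid: pd.DataFrame  # rows: bp percentile (int), cols: height percentile (int)
    unrounded: pd.DataFrame

    def cell(self, height_percentile: int, bp_percentile: int) -> int:
        return int(self.grid.loc[bp_percentile, height_percentile])

    def to_wide_csv(self, path) -> None:
        out = self.grid.copy()
        out.columns = [f"h{c:02d}" for c in out.columns]
        out.insert(0, "bp_percentile", out.index)
        out.insert(0, "model", self.model_kind)
        out.insert(0, "outcome", self.outcome)
        out.insert(0, "sex", self.sex)
        out.to_csv(path, index=False)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.grid.stack()
            .rename("bp_mmhg")
            .reset_index()
            .rename(columns={"level_1": "height_percentile"})
        )
        long.insert(0, "model", self.model_kind)
        long.insert(0, "outcome", self.outcome)
        long.insert(0, "sex", self.sex)
        return long


def build_reference_table(
    results,
    height_ps=HEIGHT_PERCENTILES,
    bp_ps=BP_PERCENTILES,
    sex: str | None = None,
    outcome: str | None = None,
    allow_extrapolation: bool = True,
) -> ReferenceTable:
    """Tabulate a fitted model (LMS or polynomial) on the reference grid.

    ``results`` must expose ``centile(p, zht)``; LMS results additionally
    accept ``allow_extrapolation`` (curves held flat beyond the fitted
    Zht range — the outermost grid columns sit at |Zht| = 1.64, inside
    any realistically sized fit).

    Raises ``ValueError`` if the unrounded cells are not strictly
    increasing in BP percentile at any height column.
    """
    height_ps = list(height_ps)
    bp_ps = list(bp_ps)
    if any(not 0 < p < 1 for p in height_ps + bp_ps):
        raise ValueError("percentiles must lie in (0, 1)")
    zhts = np.array([zht_from_height_percentile(p) for p in height_ps])
    cells = np.empty((len(bp_ps), len(height_ps)))
    for i, p in enumerate(bp_ps):
        try:
            if hasattr(results, "curves"):  # LMS results
                cells[i] = results.centile(p, zhts, allow_extrapolation=allow_extrapolation)
            else:
                cells[i] = results.centile(p, zhts)
        except ValueError as exc:
            raise ValueError(f"centile failed at bp percentile {p}: {exc}") from exc
    unrounded = pd.DataFrame(
        cells,
        index=pd.Index([int(round(p * 100)) for p in bp_ps], name="bp_percentile"),
        columns=pd.Index([int(round(p * 100)) for p in height_ps], name="height_percentile"),
    )
    if not np.all(np.diff(cells, axis=0) > 0):
        raise ValueError("centiles are not strictly increasing in BP percentile")
    grid = unrounded.apply(lambda col: round_half_up(col.to_numpy()))
    kind = "lms" if hasattr(results, "curves") else "polynomial"
    return ReferenceTable(
        sex=sex if sex is not None else getattr(results, "sex", ""),
        outcome=outcome if outcome is not None else getattr(results, "outcome", ""),
        model_kind=kind,
        grid=grid,
        unrounded=unrounded,
    )


def compare_tables(a: ReferenceTable, b: ReferenceTable) -> dict:
    """Cellwise differences a - b with max and mean absolute difference."""
    if not a.grid.index.equals(b.grid.index) or not a.grid.columns.equals(b.grid.columns):
        raise ValueError("tables have mismatched grids")
    diff = a.grid - b.grid
    return {
        "diff": diff,
        "max_abs": int(diff.abs().to_numpy().max()),
        "mean_abs": float(diff.abs().to_numpy().mean()),
    }
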