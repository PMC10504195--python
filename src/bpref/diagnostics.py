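"""Fit-diagnostic data products.

The published analysis judged model fit from three visual checks —
observed-vs-fitted centile curves, residual density and a normal Q–Q
plot.  The testable artifact is the plotted coordinates, so this module
emits tidy data (render externally or with any plotting library).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["qq_coordinates", "fitcurve_data", "residual_density"]

log = logging.getLogger(__name__)


def qq_coordinates(z_residuals) -> pd.DataFrame:
    """Normal Q–Q coordinates at plotting positions (i - 0.5)/n.

    Returns a DataFrame with ``theoretical`` (normal quantiles) and
    ``sample`` (sorted residuals).  Warns when the residuals are
    degenerate (constant).
    """
    z = np.sort(np.asarray(z_residuals, dtype=float))
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 residuals for a Q-Q plot")
    if np.ptp(z) == 0:
        log.warning("constant residual vector: Q-Q sample side is degenerate")
    pp = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame({"theoretical": norm.ppf(pp), "sample": z})


def residual_density(z_residuals, bins: int = 40) -> pd.DataFrame:
    """Histogram density of residuals with the standard normal overlay."""
    z = np.asarray(z_residuals, dtype=float)
    dens, edges = np.histogram(z, bins=bins, density=True)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"z": mid, "density": dens, "normal_density": norm.pdf(mid)})


def fitcurve_data(results, zht, bp, bp_ps=(0.05, 0.50, 0.95), n_bins: int = 10,
                  min_bin_n: int = 20) -> pd.DataFrame:
    """Observed-vs-fitted centiles over equal-count Zht bins.

    Data are split into ``n_bins`` equal-count bins of Zht; per bin the
    empirical BP quantiles at ``bp_ps`` are paired with the model
    centile at the bin midpoint (median Zht of the bin).  Bins with
    fewer than ``min_bin_n`` points are merged into their left
    neighbour (logged).
    """
    zht = np.asarray(zht, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if zht.size == 0:
        raise ValueError("no data")
    order = np.argsort(zht)
    zht, bp = zht[order], bp[order]
    edges = np.linspace(0, zht.size, n_bins + 1).astype(int)
    groups = []
    start = 0
    for i in range(n_bins):
        stop = edges[i + 1]
        if stop - start < min_bin_n and groups:
            # merge small bin into previous
            log.info("merging bin %d (%d points) into neighbour", i, stop - start)
            g0, s0 = groups.pop()
            groups.append((g0, stop))
            start = stop
            continue
        if stop > start:
            groups.append((start, stop))
            start = stop
    rows = []
    for b, (i0, i1) in enumerate(groups):
        zb, yb = zht[i0:i1], bp[i0:i1]
        mid = float(np.median(zb))
        for p in bp_ps:
            if hasattr(results, "curves"):
                fitted = float(results.centile(p, mid, allow_extrapolation=True))
            else:
                fitted = float(results.centile(p, mid))
            rows.append(
                {
                    "bin": b,
                    "zht_mid": mid,
                    "n": i1 - i0,
                    "p": p,
                    "observed": float(np.quantile(yb, p)),
                    "fitted": fitted,
                }
            )
    return pd.DataFrame(rows)
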