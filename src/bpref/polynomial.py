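"""Quartic-polynomial BP reference model (normal-residual percentiles).

The comparison model used alongside the LMS fit: within each sex, BP is
regressed on height Z-score powers 1..4 by ordinary least squares, and
reference percentiles are constructed as

    centile(p | zht) = Xb(zht) + z(p) * resid_sd

where z(p) is the standard normal quantile and ``resid_sd`` the residual
standard deviation (denominator n - 5).  This mirrors the established
US fourth-report construction, restricted to a single age.  How the
original analysis derived percentiles from its polynomial fit is not
stated; the normal-residual rule adopted here is this package's
documented choice.

Sex is handled by stratification (separate fits per sex); a pooled fit
with a sex indicator is available via ``pooled=True`` on
:meth:`QuarticBPModel.from_dataframe`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = ["QuarticBPModel", "QuarticBPResults", "DEGREE"]

DEGREE = 4


class QuarticBPModel:
    """OLS model of BP on (1, Zht, Zht^2, Zht^3, Zht^4) for one stratum."""

    def __init__(self, zht, bp, sex: str = "", outcome: str = ""):
        zht = np.asarray(zht, dtype=float)
        bp = np.asarray(bp, dtype=float)
        if zht.shape != bp.shape or zht.ndim != 1:
            raise ValueError("zht and bp must be 1-d arrays of equal length")
        if len(zht) <= 10:
            raise ValueError("need more than 10 observations")
        self.zht = zht
        self.bp = bp
        self.sex = sex
        self.outcome = outcome

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bp_col="bp", zht_col="zht", **kw):
        sub = df[[zht_col, bp_col]].dropna()
        return cls(sub[zht_col].to_numpy(), sub[bp_col].to_numpy(), **kw)

    @staticmethod
    def design(zht) -> np.ndarray:
        zht = np.asarray(zht, dtype=float)
        return np.vander(zht, DEGREE + 1, increasing=True)

    def fit(self) -> "QuarticBPResults":
        X = self.design(self.zht)
        if np.linalg.matrix_rank(X) < DEGREE + 1:
            raise np.linalg.LinAlgError(
                "singular design: Zht powers are collinear (e.g. all Zht identical)"
            )
        ols = sm.OLS(self.bp, X).fit()
        resid_sd = float(np.sqrt(ols.mse_resid))  # n - 5 denominator
        return QuarticBPResults(self, ols, resid_sd)


class QuarticBPResults:
    """Fitted quartic model: coefficients b0..b4, residual SD, R^2."""

    def __init__(self, model: QuarticBPModel, ols_results, resid_sd: float):
        self.model = model
        self._ols = ols_results
        self.beta = np.asarray(ols_results.params, dtype=float)
        self.bse = np.asarray(ols_results.bse, dtype=float)
        self.resid_sd = resid_sd
        self.n_fit = len(model.zht)
        self.r_squared = float(ols_results.rsquared)
        self.sex = model.sex
        self.outcome = model.outcome

    def predict_mean(self, zht):
        z = np.atleast_1d(np.asarray(zht, dtype=float))
        out = QuarticBPModel.design(z) @ self.beta
        return out if np.ndim(zht) else float(out[0])

    def centile(self, p, zht):
        """Reference percentile: predicted mean + z(p) * resid_sd."""
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("p must lie in (0, 1)")
        out = self.predict_mean(np.atleast_1d(np.asarray(zht, float)))
        out = out + norm.ppf(p) * self.resid_sd
        return out if (np.ndim(zht) or p.ndim) else float(np.asarray(out).reshape(-1)[0])

    def summary(self) -> str:
        lines = [
            "Quartic polynomial BP reference model",
            f"  stratum  : {self.sex or '-'} / {self.outcome or '-'}",
            f"  n        : {self.n_fit}",
            f"  R^2      : {self.r_squared:.4f}",
            f"  resid SD : {self.resid_sd:.3f} mmHg",
            "  coefficients (mmHg per Zht^k):",
        ]
        for k, (b, se) in enumerate(zip(self.beta, self.bse)):
            lines.append(f"    b{k}: {b:10.4f}  (se {se:.4f})")
        return "\n".join(lines)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": [f"zht^{k}" for k in range(DEGREE + 1)],
                "coef": self.beta,
                "se": self.bse,
            }
        ).assign(resid_sd=self.resid_sd, n=self.n_fit)

    def export(self, csv_path) -> None:
        self.coef_table().to_csv(csv_path, index=False)

    @classmethod
    def from_export(cls, csv_path) -> "QuarticBPResults":
        t = pd.read_csv(csv_path, float_precision="round_trip")
        obj = cls.__new__(cls)
        obj.model = None
        obj._ols = None
        obj.beta = t["coef"].to_numpy(dtype=float)
        obj.bse = t["se"].to_numpy(dtype=float)
        obj.resid_sd = float(t["resid_sd"].iloc[0])
        obj.n_fit = int(t["n"].iloc[0])
        obj.r_squared = np.nan
        obj.sex = ""
        obj.outcome = ""
        return obj
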