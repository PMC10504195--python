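"""Sex-stratified LMS (BCCG) centile surfaces over height Z-score.

The model: at height Z-score ``x``, blood pressure follows a Box–Cox–
Cole–Green distribution with smoothly varying parameters L(x) (Box–Cox
power), M(x) (median) and S(x) (coefficient of variation).  The three
curves are penalized B-splines whose flexibility is fixed in equivalent
degrees of freedom (edf); curves are estimated by penalized maximum
likelihood, and the edf combination is chosen by minimum BIC over a
grid, BIC = -2*loglik + log(n) * (total edf).

Conventions (the published analysis names only "a generalized additive
model using the LMS method", so these are this package's documented
choices):

* M and S are modelled on the log scale (positivity by construction);
  L is modelled on the identity scale.
* edf = 1 means a constant curve, edf = 2 exactly linear; for edf > 2 a
  cubic P-spline is used whose roughness penalty is calibrated so that
  the unweighted smoother trace equals the requested edf.
* The likelihood is maximized jointly over all three coefficient
  vectors (L-BFGS with analytic gradients); the reported log-likelihood
  is the unpenalized one at the penalized optimum.
* The fitter is deterministic given data and grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .bccg import bccg_centile, bccg_zscore

__all__ = ["LMSModel", "LMSResults", "ConvergenceError", "default_edf_grid"]

_L_EPS = 1e-8


class ConvergenceError(RuntimeError):
    """Penalized-likelihood optimization failed to converge."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def default_edf_grid() -> list[tuple[float, float, float]]:
    """Default (edf_L, edf_M, edf_S) grid: L constant or linear, M up to
    5 edf, S up to 3 edf."""
    return [
        (eL, eM, eS)
        for eL in (1, 2)
        for eM in (2, 3, 4, 5)
        for eS in (1, 2, 3)
    ]


# --------------------------------------------------------------------------
# curve bases


@dataclass
class _Basis:
    """Design matrix + roughness penalty realizing a requested edf."""

    kind: str  # constant | linear | pspline
    edf: float
    knots: np.ndarray  # full B-spline knot vector (empty for const/linear)
    lam: float
    x_range: tuple

    def design(self, x):
        x = np.clip(np.asarray(x, dtype=float), *self.x_range)
        if self.kind == "constant":
            return np.ones((x.size, 1))
        if self.kind == "linear":
            return np.column_stack([np.ones(x.size), x])
        return BSpline.design_matrix(x, self.knots, 3).toarray()

    @property
    def n_coef(self):
        if self.kind == "constant":
            return 1
        if self.kind == "linear":
            return 2
        return len(self.knots) - 4

    def penalty(self):
        k = self.n_coef
        if self.kind != "pspline" or self.lam == 0:
            return np.zeros((k, k))
        D = np.diff(np.eye(k), n=2, axis=0)
        return self.lam * (D.T @ D)


def _make_basis(x, edf, n_basis=8) -> _Basis:
    """Construct the basis realizing ``edf`` equivalent degrees of freedom."""
    x = np.asarray(x, dtype=float)
    rng = (float(x.min()), float(x.max()))
    if edf <= 1:
        return _Basis("constant", 1.0, np.array([]), 0.0, rng)
    if edf <= 2:
        return _Basis("linear", 2.0, np.array([]), 0.0, rng)
    k = max(n_basis, int(np.ceil(edf)) + 3)
    # interior knots at equally spaced quantiles of x
    n_int = k - 4
    qs = np.linspace(0, 1, n_int + 2)[1:-1]
    interior = np.quantile(x, qs)
    lo, hi = rng
    interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    B = BSpline.design_matrix(x, t, 3).toarray()
    BtB = B.T @ B
    D = np.diff(np.eye(k), n=2, axis=0)
    P = D.T @ D

    def trace_edf(lam):
        return float(np.trace(np.linalg.solve(BtB + lam * P + 1e-10 * np.eye(k), BtB)))

    lo_l, hi_l = 1e-8, 1e12
    if trace_edf(lo_l) < edf:
        lam = lo_l
    else:
        for _ in range(200):
            mid = np.sqrt(lo_l * hi_l)
            if trace_edf(mid) > edf:
                lo_l = mid
            else:
                hi_l = mid
            if hi_l / lo_l < 1 + 1e-10:
                break
        lam = np.sqrt(lo_l * hi_l)
    return _Basis("pspline", float(edf), t, float(lam), rng)


# --------------------------------------------------------------------------
# likelihood


def _negloglik_and_grad(theta, splits, B_L, B_M, B_S, P_L, P_M, P_S, logy):
    cL = theta[: splits[0]]
    cM = theta[splits[0] : splits[1]]
    cS = theta[splits[1] :]
    Lv = B_L @ cL
    etaM = B_M @ cM
    etaS = B_S @ cS
    S = np.exp(etaS)
    logr = logy - etaM
    small = np.abs(Lv) < _L_EPS
    Lsafe = np.where(small, 1.0, Lv)
    t = np.exp(Lv * logr)
    z = np.where(small, logr / S, (t - 1.0) / (Lsafe * S))
    ll = Lv * logr - etaS - 0.5 * z**2  # constants dropped
    # pointwise gradients
    gM = -Lv + z * t / S
    gS = z * z - 1.0
    dzdL = np.where(
        small,
        logr * logr / (2.0 * S),
        (t * logr) / (Lsafe * S) - z / Lsafe,
    )
    gL = logr - z * dzdL
    nll = -float(np.sum(ll))
    nll += 0.5 * (cL @ P_L @ cL + cM @ P_M @ cM + cS @ P_S @ cS)
    grad = np.concatenate(
        [
            -(B_L.T @ gL) + P_L @ cL,
            -(B_M.T @ gM) + P_M @ cM,
            -(B_S.T @ gS) + P_S @ cS,
        ]
    )
    return nll, grad


# --------------------------------------------------------------------------
# model / results


class LMSModel:
    """LMS (BCCG) centile model of BP over height Z-score for one
    sex × outcome stratum.

    Parameters
    ----------
    zht : array_like
        Height Z-scores (finite).
    bp : array_like
        Selected BP values, mmHg (> 0).
    sex, outcome : str, optional
        Labels carried into results and exports.
    min_n : int
        Refuse to fit below this sample size (default 50).
    """

    def __init__(self, zht, bp, sex: str = "", outcome: str = "", min_n: int = 50, n_basis: int = 8):
        zht = np.asarray(zht, dtype=float)
        bp = np.asarray(bp, dtype=float)
        if zht.shape != bp.shape or zht.ndim != 1:
            raise ValueError("zht and bp must be 1-d arrays of equal length")
        if len(zht) < min_n:
            raise ValueError(f"need at least {min_n} observations, got {len(zht)}")
        if not np.all(np.isfinite(zht)):
            raise ValueError("zht must be finite")
        if not np.all(bp > 0):
            raise ValueError("bp must be positive")
        self.zht = zht
        self.bp = bp
        self.sex = sex
        self.outcome = outcome
        self.n_basis = n_basis

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bp_col: str = "bp", zht_col: str = "zht", **kw):
        sub = df[[zht_col, bp_col]].dropna()
        return cls(sub[zht_col].to_numpy(), sub[bp_col].to_numpy(),
                   sex=kw.pop("sex", str(df["sex"].iloc[0]) if "sex" in df else ""), **kw)

    def _fit_one(self, edf_triple, maxiter=400):
        eL, eM, eS = edf_triple
        bL = _make_basis(self.zht, eL, self.n_basis)
        bM = _make_basis(self.zht, eM, self.n_basis)
        bS = _make_basis(self.zht, eS, self.n_basis)
        B_L, B_M, B_S = bL.design(self.zht), bM.design(self.zht), bS.design(self.zht)
        P_L, P_M, P_S = bL.penalty(), bM.penalty(), bS.penalty()
        logy = np.log(self.bp)

        # initialization: L = 1, log M from penalized LS on log y, S constant
        # at a robust CV estimate
        cL0 = _const_coefs(bL, 1.0)
        A = B_M.T @ B_M + P_M + 1e-10 * np.eye(B_M.shape[1])
        cM0 = np.linalg.solve(A, B_M.T @ logy)
        med = np.median(self.bp)
        iqr = np.subtract(*np.percentile(self.bp, [75, 25]))
        cv0 = max(iqr / 1.349 / med, 1e-3)
        cS0 = _const_coefs(bS, np.log(cv0))
        theta0 = np.concatenate([cL0, cM0, cS0])
        splits = (len(cL0), len(cL0) + len(cM0))

        res = minimize(
            _negloglik_and_grad,
            theta0,
            args=(splits, B_L, B_M, B_S, P_L, P_M, P_S, logy),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if not np.isfinite(res.fun) or (not res.success and gnorm > 1e-2 * len(self.zht)):
            raise ConvergenceError(
                f"LMS fit did not converge for edf {edf_triple}: {res.message}",
                diagnostics={"grad_max": gnorm, "nll": float(res.fun), "nit": res.nit},
            )
        theta = res.x
        cL = theta[: splits[0]]
        cM = theta[splits[0] : splits[1]]
        cS = theta[splits[1] :]
        # unpenalized log-likelihood with density constants restored
        Lv = B_L @ cL
        etaM = B_M @ cM
        etaS = B_S @ cS
        z = _z_of(logy, Lv, etaM, np.exp(etaS))
        ll = float(
            np.sum(Lv * (logy - etaM) - logy - etaS - 0.5 * np.log(2 * np.pi) - 0.5 * z**2)
        )
        total_edf = bL.edf + bM.edf + bS.edf
        bic = -2.0 * ll + np.log(len(self.zht)) * total_edf
        return {
            "bases": (bL, bM, bS),
            "coefs": (cL, cM, cS),
            "loglik": ll,
            "bic": bic,
            "edf": (bL.edf, bM.edf, bS.edf),
            "nit": int(res.nit),
        }

    def fit(self, edf_grid: Optional[Sequence] = None, maxiter: int = 400) -> "LMSResults":
        """Fit over the edf grid and return the minimum-BIC model."""
        if edf_grid is None:
            edf_grid = default_edf_grid()
        edf_grid = list(edf_grid)
        if not edf_grid:
            raise ValueError("edf grid must be non-empty")
        fits = []
        for triple in edf_grid:
            fits.append((triple, self._fit_one(triple, maxiter=maxiter)))
        best_triple, best = min(fits, key=lambda kv: kv[1]["bic"])
        trace = pd.DataFrame(
            {
                "edf_L": [t[0] for t, _ in fits],
                "edf_M": [t[1] for t, _ in fits],
                "edf_S": [t[2] for t, _ in fits],
                "loglik": [f["loglik"] for _, f in fits],
                "bic": [f["bic"] for _, f in fits],
            }
        )
        return LMSResults(self, best, trace)


class LMSResults:
    """Fitted LMS centile surface: L/M/S curves, edf, BIC, diagnostics."""

    def __init__(self, model: LMSModel, fit: dict, bic_trace: pd.DataFrame):
        self.model = model
        self._bases = fit["bases"]
        self._coefs = fit["coefs"]
        self.loglik = fit["loglik"]
        self.bic = fit["bic"]
        self.edf = fit["edf"]
        self.n_fit = len(model.zht)
        self.bic_trace = bic_trace
        self.sex = model.sex
        self.outcome = model.outcome
        self.zht_range = (float(model.zht.min()), float(model.zht.max()))

    # -- curve evaluation ---------------------------------------------------

    def _check_range(self, zht, allow_extrapolation):
        zht = np.asarray(zht, dtype=float)
        lo, hi = self.zht_range
        if not allow_extrapolation and (np.any(zht < lo) or np.any(zht > hi)):
            raise ValueError(
                f"zht outside fitted range [{lo:.3f}, {hi:.3f}]; "
                "pass allow_extrapolation=True to hold curves flat beyond it"
            )
        return zht

    def curves(self, zht, allow_extrapolation: bool = False):
        """Evaluate (L, M, S) at ``zht``.  Beyond the fitted range the
        curves are held flat (only with ``allow_extrapolation``)."""
        zht = self._check_range(zht, allow_extrapolation)
        scalar = np.ndim(zht) == 0
        zht = np.atleast_1d(zht)
        bL, bM, bS = self._bases
        cL, cM, cS = self._coefs
        L = bL.design(zht) @ cL
        M = np.exp(bM.design(zht) @ cM)
        S = np.exp(bS.design(zht) @ cS)
        if scalar:
            return float(L[0]), float(M[0]), float(S[0])
        return L, M, S

    def centile(self, p, zht, allow_extrapolation: bool = False):
        """BP centile at probability ``p`` and height Z-score ``zht``."""
        L, M, S = self.curves(zht, allow_extrapolation)
        return bccg_centile(p, L, M, S)

    def z_residuals(self, zht=None, bp=None, allow_extrapolation: bool = False):
        """Per-observation BCCG z-scores under the fitted curves.

        Defaults to the training data.  Observations outside the fitted
        Zht range are excluded; returns ``(z, n_excluded)``.
        """
        if zht is None:
            zht, bp = self.model.zht, self.model.bp
        zht = np.asarray(zht, dtype=float)
        bp = np.asarray(bp, dtype=float)
        lo, hi = self.zht_range
        inside = (zht >= lo) & (zht <= hi) if not allow_extrapolation else np.ones_like(zht, bool)
        L, M, S = self.curves(zht[inside], allow_extrapolation=True)
        z = bccg_zscore(bp[inside], L, M, S)
        return np.atleast_1d(z), int((~inside).sum())

    # -- presentation / export ----------------------------------------------

    def summary(self) -> str:
        lines = [
            "LMS (BCCG) centile model",
            f"  stratum      : {self.sex or '-'} / {self.outcome or '-'}",
            f"  n            : {self.n_fit}",
            f"  edf (L, M, S): {self.edf}",
            f"  loglik       : {self.loglik:.2f}",
            f"  BIC          : {self.bic:.2f}",
            f"  Zht range    : [{self.zht_range[0]:.2f}, {self.zht_range[1]:.2f}]",
            "  centiles at Zht = 0:",
        ]
        for p in (0.05, 0.50, 0.95):
            z0 = np.clip(0.0, *self.zht_range)
            lines.append(f"    p={p:4.2f}: {float(self.centile(p, z0)):7.1f} mmHg")
        return "\n".join(lines)

    def coef_table(self) -> pd.DataFrame:
        rows = []
        for name, basis, coef in zip("LMS", self._bases, self._coefs):
            for i, c in enumerate(coef):
                rows.append(
                    {
                        "curve": name,
                        "kind": basis.kind,
                        "index": i,
                        "coef": c,
                        "lam": basis.lam,
                        "edf": basis.edf,
                    }
                )
        return pd.DataFrame(rows)

    def export(self, csv_path, json_path) -> None:
        """Write the coefficient/knot table (CSV) and fit metadata (JSON).

        Floats are written at full shortest-repr precision, so a model
        reloaded with :meth:`from_export` evaluates bit-identically.
        """
        self.coef_table().to_csv(csv_path, index=False)
        meta = {
            "sex": self.sex,
            "outcome": self.outcome,
            "n_fit": self.n_fit,
            "edf": list(self.edf),
            "loglik": self.loglik,
            "bic": self.bic,
            "zht_range": list(self.zht_range),
            "bases": [
                {
                    "curve": name,
                    "kind": b.kind,
                    "knots": b.knots.tolist(),
                    "lam": b.lam,
                    "edf": b.edf,
                    "x_range": list(b.x_range),
                }
                for name, b in zip("LMS", self._bases)
            ],
            "coefs": [c.tolist() for c in self._coefs],
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_export(cls, json_path) -> "LMSResults":
        with open(json_path) as fh:
            meta = json.load(fh)
        bases = tuple(
            _Basis(
                kind=b["kind"],
                edf=b["edf"],
                knots=np.asarray(b["knots"], dtype=float),
                lam=b["lam"],
                x_range=tuple(b["x_range"]),
            )
            for b in meta["bases"]
        )
        coefs = tuple(np.asarray(c, dtype=float) for c in meta["coefs"])
        obj = cls.__new__(cls)
        obj.model = None
        obj._bases = bases
        obj._coefs = coefs
        obj.loglik = meta["loglik"]
        obj.bic = meta["bic"]
        obj.edf = tuple(meta["edf"])
        obj.n_fit = meta["n_fit"]
        obj.bic_trace = None
        obj.sex = meta["sex"]
        obj.outcome = meta["outcome"]
        obj.zht_range = tuple(meta["zht_range"])
        return obj


def _const_coefs(basis: _Basis, value: float) -> np.ndarray:
    """Coefficients representing the constant function ``value``."""
    if basis.kind == "constant":
        return np.array([value])
    if basis.kind == "linear":
        return np.array([value, 0.0])
    # B-splines form a partition of unity
    return np.full(basis.n_coef, value)


def _z_of(logy, Lv, etaM, S):
    logr = logy - etaM
    small = np.abs(Lv) < _L_EPS
    Lsafe = np.where(small, 1.0, Lv)
    t = np.exp(Lv * logr)
    return np.where(small, logr / S, (t - 1.0) / (Lsafe * S))
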