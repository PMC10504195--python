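"""Box–Cox–Cole–Green (BCCG) distribution primitives.

The BCCG family underlies the LMS method for centile-curve construction:
a positive measurement ``y`` is described by three parameters — the
Box–Cox power ``L`` (skewness), the median ``M`` and the coefficient of
variation ``S`` — such that

    z = ((y / M)**L - 1) / (L * S)        (L != 0)
    z = log(y / M) / S                    (L == 0)

is (approximately) standard normal.  Centiles are then closed-form
functions of (L, M, S), which is what makes the method attractive for
reference charts.

This module provides the forward transform (:func:`bccg_zscore`), its
inverse (:func:`bccg_centile`), the log-density used by the fitter, and
:func:`calibrate_from_quantiles`, which recovers (L, M, S) from a set of
printed quantiles — the mechanism used to build generator truth surfaces
from a published reference table.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import norm

__all__ = [
    "bccg_zscore",
    "bccg_centile",
    "bccg_logpdf",
    "calibrate_from_quantiles",
    "CalibrationError",
]

#: below this magnitude L is treated as 0 (log-normal limit)
_L_EPS = 1e-8


class CalibrationError(ValueError):
    """Quantile-matching calibration could not produce a valid (L, M, S)."""


def bccg_zscore(y, L, M, S):
    """Transform measurement(s) ``y`` to BCCG z-score(s).

    Parameters
    ----------
    y : array_like
        Positive measurement values (e.g. mmHg).
    L, M, S : array_like
        Box–Cox power, median (>0) and coefficient of variation (>0).
        Broadcast against ``y``.

    Returns
    -------
    ndarray or float
        z = ((y/M)**L - 1)/(L*S) for L != 0, log(y/M)/S for L == 0.
    """
    y = np.asarray(y, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be positive")
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    logr = np.log(y) - np.log(M)
    Lsafe = np.where(np.abs(L) < _L_EPS, 1.0, L)
    z_pow = (np.exp(Lsafe * logr) - 1.0) / (Lsafe * S)
    z_log = logr / S
    out = np.where(np.abs(L) < _L_EPS, z_log, z_pow)
    return out if out.ndim else float(out)


def bccg_centile(p, L, M, S):
    """Evaluate the BCCG quantile function at probability ``p``.

    Returns M*(1 + L*S*z(p))**(1/L) for L != 0 and M*exp(S*z(p)) for
    L == 0, where z(p) is the standard normal quantile.  Raises
    ``ValueError`` when 1 + L*S*z(p) <= 0 (outside the distribution's
    support).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie in (0, 1)")
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    z = norm.ppf(p)
    base = 1.0 + L * S * z
    small = np.abs(L) < _L_EPS
    if np.any(~small & (base <= 0)):
        raise ValueError("centile outside BCCG support: 1 + L*S*z(p) <= 0")
    Lsafe = np.where(small, 1.0, L)
    with np.errstate(invalid="ignore"):
        q_pow = M * np.power(np.where(small, 1.0, base), 1.0 / Lsafe)
    q_log = M * np.exp(S * z)
    out = np.where(small, q_log, q_pow)
    return out if out.ndim else float(out)


def bccg_logpdf(y, L, M, S):
    """Pointwise BCCG log-density (truncation term for y>0 ignored).

    log f(y) = (L-1) log y - L log M - log S - log(2*pi)/2 - z**2/2.

    The omitted truncation correction, -log Phi(1/(S|L|)), is negligible
    for the small S typical of anthropometric and BP data.
    """
    y = np.asarray(y, dtype=float)
    z = bccg_zscore(y, L, M, S)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    return (
        L * (np.log(y) - np.log(M))
        - np.log(y)
        - np.log(S)
        - 0.5 * np.log(2.0 * np.pi)
        - 0.5 * z**2
    )


def calibrate_from_quantiles(probs, quantiles, fix_L=None, l_bounds=(-5.0, 5.0),
                             polish=False):
    """Recover (L, M, S) from quantiles of a BCCG distribution.

    The median quantile (p = 0.5), when present, pins M analytically —
    the 50th centile of a BCCG equals M.  The remaining parameters are
    found by least squares on the quantile mismatch; with
    ``polish=True`` an over-determined fit is additionally refined
    toward the Chebyshev (minimax) solution, shrinking the worst-case
    mismatch at the cost of the mean-square one.  With exactly three
    quantiles the system is exactly determined and the residuals vanish
    to solver tolerance.

    Parameters
    ----------
    probs : sequence of float
        At least 2 distinct probabilities in (0, 1); at least 3 unless
        ``fix_L`` is given.
    quantiles : sequence of float
        Strictly increasing positive quantile values, same length.
    fix_L : float, optional
        Hold the Box–Cox power fixed (e.g. ``fix_L=1`` for the normal
        case) and solve only for the scale.
    l_bounds : (float, float)
        Search interval for L.
    polish : bool
        Apply the minimax refinement to over-determined fits.

    Returns
    -------
    (L, M, S) : tuple of float

    Raises
    ------
    CalibrationError
        Non-monotone quantiles, too few points, or no solution with
        L inside ``l_bounds``.
    """
    probs = np.asarray(probs, dtype=float)
    quantiles = np.asarray(quantiles, dtype=float)
    if probs.shape != quantiles.shape:
        raise CalibrationError("probs and quantiles must have the same length")
    if np.any((probs <= 0) | (probs >= 1)):
        raise CalibrationError("probs must lie in (0, 1)")
    order = np.argsort(probs)
    probs, quantiles = probs[order], quantiles[order]
    if len(np.unique(probs)) != len(probs):
        raise CalibrationError("probs must be distinct")
    if np.any(np.diff(quantiles) <= 0):
        raise CalibrationError("quantiles must be strictly increasing in p")
    if np.any(quantiles <= 0):
        raise CalibrationError("quantiles must be positive")
    n_free = 2 if fix_L is None else 1
    if len(probs) < n_free + 1:
        raise CalibrationError("not enough quantiles to identify the parameters")

    has_median = np.any(np.isclose(probs, 0.5))
    if has_median:
        M0 = float(quantiles[np.argmin(np.abs(probs - 0.5))])
    else:
        # crude start; M becomes a free parameter below
        M0 = float(np.interp(0.5, probs, quantiles))

    zp = norm.ppf(probs)

    def q_of(L, M, S):
        base = 1.0 + L * S * zp
        if abs(L) < _L_EPS:
            return M * np.exp(S * zp)
        if np.any(base <= 0):
            return np.full_like(zp, np.nan)
        return M * np.power(base, 1.0 / L)

    # layout of the free-parameter vector
    def unpack(x):
        if fix_L is not None:
            L = float(fix_L)
            S = x[0]
            M = x[1] if not has_median else M0
        else:
            L, S = x[0], x[1]
            M = x[2] if not has_median else M0
        return L, M, S

    def resid(x):
        L, M, S = unpack(x)
        q = q_of(L, M, S)
        r = q - quantiles
        return np.where(np.isfinite(r), r, 1e6)

    # starting scale from the normal approximation
    slope = np.polyfit(zp, quantiles, 1)[0]
    S0 = max(slope / M0, 1e-4)
    if fix_L is None:
        x0 = [1.0, S0] if has_median else [1.0, S0, M0]
        lo = [l_bounds[0], 1e-6] + ([] if has_median else [1e-6])
        hi = [l_bounds[1], 2.0] + ([] if has_median else [np.inf])
    else:
        x0 = [S0] if has_median else [S0, M0]
        lo = [1e-6] + ([] if has_median else [1e-6])
        hi = [2.0] + ([] if has_median else [np.inf])

    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
    x = sol.x
    if polish and len(probs) > n_free + (0 if has_median else 1):
        # over-determined: polish toward the minimax solution
        pol = minimize(
            lambda v: float(np.max(np.abs(resid(v)))),
            x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        if np.max(np.abs(resid(pol.x))) < np.max(np.abs(resid(x))):
            x = pol.x
    L, M, S = unpack(x)
    if not (l_bounds[0] <= L <= l_bounds[1]) or S <= 0 or M <= 0:
        raise CalibrationError("no valid (L, M, S) found within bounds")
    # exactly determined systems must actually be solved
    if len(probs) == n_free + (0 if has_median else 1):
        if np.max(np.abs(resid(x))) > 0.01:
            raise CalibrationError(
                "calibration failed: residual %.3g exceeds tolerance"
                % np.max(np.abs(resid(x)))
            )
    return float(L), float(M), float(S)
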