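"""Michaelis-Menten and linear dose-response fits.

Covers three uses of the same machinery: actin-activated Mg-ATPase rate
versus [actin] (after basal subtraction), the optimal-power frequency
f_max versus [ATP] (both Michaelis-Menten), and f_max versus [Pi]
(ordinary least squares, with a t-test on the slope).  Catalytic
efficiency is V_max/K_m.

Fitting is unweighted nonlinear least squares, initialized at
vmax0 = max(y) and km0 = the concentration where y first reaches half of
max(y).  A fitted K_m approaching the upper bound (100x the largest
concentration) is flagged unidentifiable: the data do not saturate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

KM_BOUND_FACTOR = 100.0


@dataclass
class MMFit:
    """Michaelis-Menten parameters with standard errors."""

    vmax: float
    km: float
    se_vmax: float
    se_km: float
    n_points: int
    unidentifiable: bool = False

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency V_max / K_m."""
        return self.vmax / self.km

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.vmax * x / (self.km + x)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


def _mm(x, vmax, km):
    return vmax * x / (km + x)


def fit_mm(x, y, basal: float | None = None) -> MMFit:
    """Nonlinear least-squares fit of y = vmax x / (km + x).

    ``basal`` (e.g. basal Mg-ATPase) is subtracted from all responses
    before fitting, mirroring the experimental treatment; fitting
    pre-subtracted data gives the identical result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.unique(x[x > 0]).size < 3:
        raise ValueError("need at least 3 distinct positive concentrations")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if basal is not None:
        y = y - basal
    ymax = float(np.max(y))
    if ymax <= 0:
        raise ValueError("responses are non-positive after basal subtraction")
    half_idx = np.flatnonzero(y >= ymax / 2.0)
    km0 = float(x[half_idx[0]]) if half_idx.size and x[half_idx[0]] > 0 else float(np.median(x[x > 0]))
    km_hi = KM_BOUND_FACTOR * float(np.max(x))
    try:
        popt, pcov = curve_fit(_mm, x, y, p0=[ymax, km0],
                               bounds=([1e-12, 1e-12], [np.inf, km_hi]),
                               maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    # data that never approach saturation cannot pin km
    unident = bool(popt[1] > 10.0 * float(np.max(x)))
    return MMFit(vmax=float(popt[0]), km=float(popt[1]),
                 se_vmax=float(se[0]), se_km=float(se[1]),
                 n_points=int(x.size), unidentifiable=unident)


def catalytic_efficiency(fit: MMFit) -> float:
    """V_max / K_m from one fit.

    Note: published efficiencies are often means of per-preparation
    ratios; the ratio of pooled fit parameters is a different estimator
    and need not match such a mean.  Use ``per_replicate_efficiency`` for
    the per-preparation version.
    """
    return fit.efficiency


def per_replicate_efficiency(fits) -> tuple[float, float]:
    """Mean and SD of per-replicate V_max/K_m ratios."""
    ratios = np.array([f.efficiency for f in fits], dtype=float)
    return float(np.mean(ratios)), float(np.std(ratios, ddof=1))


def fit_fmax_vs_atp(atp_mM, fmax_hz) -> MMFit:
    """Michaelis-Menten fit of the optimal-power frequency versus [ATP]."""
    return fit_mm(atp_mM, fmax_hz, basal=None)


def fit_fmax_vs_atp_per_fiber(df: pd.DataFrame, fiber_col: str = "fiber",
                              x_col: str = "atp_mM",
                              y_col: str = "fmax_hz") -> pd.DataFrame:
    """Fit each fiber separately; one parameter row per fiber.

    Complements the pooled fit: whether parameters should be estimated
    per fiber then averaged, or from pooled means, is a design choice the
    caller makes; both modes are offered.
    """
    rows = []
    for fiber, sub in df.groupby(fiber_col):
        fit = fit_fmax_vs_atp(sub[x_col].to_numpy(), sub[y_col].to_numpy())
        rows.append({fiber_col: fiber, "vmax": fit.vmax, "km": fit.km,
                     "efficiency": fit.efficiency,
                     "unidentifiable": fit.unidentifiable})
    return pd.DataFrame(rows)


def fit_fmax_vs_pi(pi_mM, fmax_hz) -> LinearFit:
    """Ordinary least squares of f_max on [Pi] with a slope t-test."""
    x = np.asarray(pi_mM, dtype=float)
    y = np.asarray(fmax_hz, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate concentrations: zero spread")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue**2), p_slope=float(res.pvalue))


def summarize_replicates(values) -> tuple[float, float]:
    """Plain replicate mean and SD (for rates reported without fitting)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    return float(np.mean(v)), float(np.std(v, ddof=1))
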