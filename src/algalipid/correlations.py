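"""Empirical correlations linking initial nitrogen to batch outcomes.

Across the HA-1 nitrogen series, the fitted carrying capacity follows a
quadratic in the initial NaNO3 charge,

    Xmax(N0) = a2*N0^2 + a1*N0 + a0,

and the lag parameter h0 decreases roughly linearly with N0.  Combining
the quadratic with the lipid law at full nitrogen depletion (N -> 0,
X -> Xmax) gives a closed-form final lipid content

    Lf(N0) = (1 - c) - k*(N0 + Phi) / Xmax(N0),

which is the practical planning tool: pick N0, read off expected peak
biomass and final lipid fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuadraticFit",
    "LinearFit",
    "fit_xmax_quadratic",
    "fit_h0_linear",
    "predict_xmax",
    "final_lipid",
    "relative_increase",
    "ExtrapolationWarning",
]


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted N0 range (+/- 20%)."""


def _r_squared(y, yhat) -> float:
    y = np.asarray(y, float)
    resid = y - np.asarray(yhat, float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class QuadraticFit:
    """OLS quadratic Xmax(N0) = a2*N0^2 + a1*N0 + a0 with its R^2 and range."""

    a2: float
    a1: float
    a0: float
    r_squared: float
    n: int
    n0_min: float
    n0_max: float

    def __call__(self, N0):
        return self.a2 * np.asarray(N0, float) ** 2 + self.a1 * np.asarray(N0, float) + self.a0


@dataclass(frozen=True)
class LinearFit:
    """OLS line y = slope*N0 + intercept with its R^2."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def __call__(self, N0):
        return self.slope * np.asarray(N0, float) + self.intercept


def fit_xmax_quadratic(pairs) -> QuadraticFit:
    """Ordinary least-squares degree-2 polynomial through (N0, Xmax) pairs.

    Unweighted fit on the raw pairs (per-condition means); requires at least
    three distinct N0 values for a full-rank design.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (N0, Xmax) pairs")
    n0, y = arr[:, 0], arr[:, 1]
    if len(np.unique(n0)) < 3:
        raise ValueError("need >= 3 distinct N0 values for a quadratic fit")
    a2, a1, a0 = np.polyfit(n0, y, 2)
    yhat = np.polyval([a2, a1, a0], n0)
    return QuadraticFit(
        a2=float(a2),
        a1=float(a1),
        a0=float(a0),
        r_squared=_r_squared(y, yhat),
        n=len(n0),
        n0_min=float(n0.min()),
        n0_max=float(n0.max()),
    )


def fit_h0_linear(pairs) -> LinearFit:
    """Ordinary least-squares line through (N0, h0) pairs (>= 2 distinct N0)."""
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (N0, h0) pairs")
    n0, y = arr[:, 0], arr[:, 1]
    if len(np.unique(n0)) < 2:
        raise ValueError("need >= 2 distinct N0 values for a line")
    slope, intercept = np.polyfit(n0, y, 1)
    yhat = slope * n0 + intercept
    return LinearFit(
        slope=float(slope), intercept=float(intercept), r_squared=_r_squared(y, yhat), n=len(n0)
    )


def predict_xmax(N0, fit: QuadraticFit) -> float:
    """Evaluate the quadratic at N0, warning outside the fitted range +/- 20%.

    The quadratic turns over and eventually goes negative, so extrapolation
    is flagged (with a warning, not an error) rather than silently trusted.
    """
    lo = fit.n0_min - 0.2 * abs(fit.n0_min)
    hi = fit.n0_max + 0.2 * abs(fit.n0_max)
    if np.any(np.asarray(N0, float) < lo) or np.any(np.asarray(N0, float) > hi):
        warnings.warn(
            f"N0={N0} outside fitted range [{fit.n0_min}, {fit.n0_max}] +/- 20%",
            ExtrapolationWarning,
            stacklevel=2,
        )
    out = fit(N0)
    return float(out) if np.ndim(N0) == 0 else out


def final_lipid(N0, k: float, c: float, phi: float, fit: QuadraticFit, *, phi_times_k: bool = True) -> float:
    """Predicted final lipid fraction at full depletion, Lf = (1-c) - k*(N0+Phi)/Xmax(N0).

    This is the lipid law evaluated at N = 0 and X = Xmax(N0) from the
    quadratic.  With ``phi_times_k=True`` (default) the additive numerator
    constant is k*phi, i.e. phi is a genuine initial internal pool; with
    ``phi_times_k=False`` the value ``phi`` is used unscaled as the additive
    constant, matching a reading where the printed constant already absorbs k.
    """
    xmax = predict_xmax(N0, fit)
    if np.any(np.asarray(xmax) <= 0):
        raise ValueError(f"predicted Xmax({N0}) = {xmax} is not positive")
    const = k * phi if phi_times_k else phi
    out = (1.0 - c) - (k * np.asarray(N0, float) + const) / xmax
    return float(out) if np.ndim(N0) == 0 else out


def relative_increase(N0_lo, N0_hi, fit: QuadraticFit) -> float:
    """Percent change of predicted Xmax from N0_lo to N0_hi: 100*(Xmax_hi/Xmax_lo - 1)."""
    lo = predict_xmax(N0_lo, fit)
    hi = predict_xmax(N0_hi, fit)
    if lo <= 0 or hi <= 0:
        raise ValueError("both predicted Xmax values must be positive")
    return 100.0 * (hi / lo - 1.0)
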