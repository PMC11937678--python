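"""Touch-typing behavioral analysis: speed-accuracy trade-off.

Accuracy as a function of the movement-time limit x is modelled as a
saturating exponential

    y(x) = a * exp(-b * x) + c

where ``b`` (1/s) is the *saturation speed*: the rate at which accuracy
plateaus as more time is allowed. Larger ``b`` means performance saturates
at shorter time limits, i.e. a resolved speed-accuracy trade-off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SATFit",
    "sat_curve",
    "select_word_lengths",
    "success_rates",
    "fit_sat_curve",
    "saturation_speed",
]

#: default parameter bounds: a in [0, 1.5], b in [0, 10], c in [0, 1]
DEFAULT_BOUNDS = ((0.0, 0.0, 0.0), (1.5, 10.0, 1.0))
#: multi-start grid over the rate parameter
B_STARTS = (0.1, 0.5, 1.0, 2.0)


def sat_curve(x, a, b, c):
    """Speed-accuracy trade-off curve ``a*exp(-b*x) + c``."""
    return a * np.exp(-b * np.asarray(x, dtype=float)) + c


@dataclass
class SATFit:
    """Fitted speed-accuracy trade-off parameters."""

    a: float
    b: float            # saturation speed, 1/s
    c: float
    rss: float          # residual sum of squares
    converged: bool

    def predict(self, x):
        return sat_curve(x, self.a, self.b, self.c)


def select_word_lengths(cpm: float, time_limit_s: float) -> tuple[int, int]:
    """Word-length bounds for a typist of the given speed.

    Capacity is the number of characters typeable within the time limit
    (``cpm / 60 * time_limit``); admissible words use 80-100% of it:
    ``[ceil(0.8*capacity), floor(capacity)]``, clamped to >= 1 character.
    If rounding empties the interval, it collapses to the nearest feasible
    length (``floor(capacity)``, clamped) with a warning.
    """
    if cpm <= 0:
        raise ValueError("characters-per-minute must be positive")
    capacity = cpm / 60.0 * time_limit_s
    lo = max(1, math.ceil(0.8 * capacity))
    hi = max(1, math.floor(capacity))
    if lo > hi:
        hi = max(1, math.floor(capacity))
        lo = hi
        warnings.warn(
            f"80-100% window empty after rounding at capacity "
            f"{capacity:.2f}; using length {hi}",
            stacklevel=2,
        )
    return lo, hi


def success_rates(table: pd.DataFrame, per_block: bool = False) -> pd.Series:
    """Per-condition success rate, pooled across blocks.

    With ``per_block=True`` the result is indexed by (block, condition)
    instead. Conditions with no trials are simply absent (a warning is
    emitted when an expected column is empty upstream of this call).
    """
    if table.empty:
        raise ValueError("behavior table is empty")
    keys = ["block", "condition_s"] if per_block else ["condition_s"]
    return table.groupby(keys)["success"].mean()


def fit_sat_curve(x, y, bounds=DEFAULT_BOUNDS, b_starts=B_STARTS) -> SATFit:
    """Nonlinear least-squares fit of the exponential trade-off curve.

    Three free parameters against (typically) three conditions make the
    fit sensitive to initialization, so a small multi-start over the rate
    parameter is used and the lowest-RSS solution returned. With exactly
    three points the fit interpolates (RSS ~ 0) whenever the data admit a
    valid parameterization within the bounds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (x, y) points")

    best: SATFit | None = None
    y_span = max(y.max() - y.min(), 1e-6)
    for b0 in b_starts:
        a0 = min(max(y_span / max(np.exp(-b0 * x.min()), 1e-12), 1e-3), 1.5)
        c0 = min(max(y.min(), 0.0), 1.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    sat_curve, x, y, p0=(a0, b0, c0), bounds=bounds,
                    maxfev=10000,
                )
        except RuntimeError:
            continue
        rss = float(np.sum((sat_curve(x, *popt) - y) ** 2))
        fit = SATFit(*map(float, popt), rss=rss, converged=True)
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        warnings.warn("SAT fit did not converge from any start", stacklevel=2)
        return SATFit(np.nan, np.nan, np.nan, rss=np.inf, converged=False)
    return best


def saturation_speed(fit: SATFit) -> float:
    """The rate parameter ``b`` of a converged fit (1/s)."""
    if not fit.converged:
        raise ValueError("cannot extract saturation speed from an "
                         "unconverged fit")
    if fit.b < 1e-6:
        warnings.warn("saturation speed at the lower boundary (b ~ 0)",
                      stacklevel=2)
    return fit.b
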