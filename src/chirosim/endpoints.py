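"""Experimental endpoint formulas and curve fits.

These are applied identically to observed and simulated emergence series:

* total mortality at test end,
  ``100 (N0 - emerged - survivors) / N0`` [%];
* mean daily mortality rate, total mortality / test duration [% d^-1];
* cumulative emergence of *surviving* individuals,
  ``100 emerged(t) / (N0 - dead_at_end)`` [%] — mortality is excluded so
  development is comparable across treatments;
* EmT50, the time to 50 % emergence, interpolated from a two-parameter
  log-logistic (Hill) curve ``y(x) = 1 / (1 + (EmT50 / x)^b)`` fitted to
  each emergence curve by binomial maximum likelihood on the per-day
  emergence increments;
* the density-mortality power law ``y = a x^b`` fitted in log-log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "EmergenceCurve",
    "EndpointResult",
    "total_mortality_pct",
    "daily_mortality_rate",
    "emergence_surv_pct",
    "log_logistic",
    "fit_emt50",
    "fit_mortality_power_law",
    "endpoints_table",
]


@dataclass(frozen=True)
class EmergenceCurve:
    """One replicate's cumulative emergence record."""

    time: np.ndarray  # d
    cumulative_emerged: np.ndarray  # counts
    n_initial: int
    n_dead_end: int  # dead at test end

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.cumulative_emerged, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "cumulative_emerged", c)
        if t.shape != c.shape:
            raise ValueError("time and cumulative_emerged must align")
        if np.any(np.diff(c) < 0):
            raise ValueError("cumulative emergence must be non-decreasing")
        if c.size and c[-1] + self.n_dead_end > self.n_initial:
            raise ValueError("emerged + dead exceeds the initial count")


@dataclass(frozen=True)
class EndpointResult:
    """All endpoint values for one (scenario, replicate)."""

    EmT50: float  # d
    slope_b: float  # -
    total_mortality_pct: float  # %
    daily_mortality_rate: float  # % d^-1
    fit_R2: float  # -
    converged: bool = True


def total_mortality_pct(n_initial: int, n_emerged: int,
                        n_survivors: int) -> float:
    """Percent mortality at test end: 100 (N0 - emerged - survivors) / N0."""
    if n_initial <= 0:
        raise ValueError("n_initial must be positive")
    if n_emerged + n_survivors > n_initial:
        raise ValueError("emerged + survivors exceeds the initial count")
    return 100.0 * (n_initial - n_emerged - n_survivors) / n_initial


def daily_mortality_rate(total_mortality: float,
                         test_duration_d: float) -> float:
    """Mean daily mortality rate [% d^-1] = total mortality / duration."""
    if test_duration_d <= 0:
        raise ValueError("test duration must be positive")
    return total_mortality / test_duration_d


def emergence_surv_pct(curve: EmergenceCurve) -> np.ndarray:
    """Cumulative emergence of surviving individuals [%] over time.

    100 emerged(t) / (N0 - dead at test end); a final value below 100 %
    means live larvae remained at test end.
    """
    denom = curve.n_initial - curve.n_dead_end
    if denom <= 0:
        raise ValueError("all individuals dead: denominator is zero")
    return 100.0 * curve.cumulative_emerged / denom


def log_logistic(x, emt50: float, b: float):
    """Two-parameter log-logistic (Hill) curve y = 1 / (1 + (EmT50/x)^b)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(x > 0, 1.0 / (1.0 + (emt50 / np.maximum(x, 1e-300))
                                     ** b), 0.0)
    return float(out) if out.ndim == 0 else out


def _binomial_nll(theta: np.ndarray, t: np.ndarray, frac: np.ndarray,
                  n: float) -> float:
    emt50, b = np.exp(theta)
    y = log_logistic(t, emt50, b)
    # interval (increment) probabilities, plus the not-yet-emerged remainder
    p = np.diff(np.concatenate([[0.0], y, [1.0]]))
    d = n * np.diff(np.concatenate([[0.0], frac, [1.0]]))
    mask = d > 0
    if np.any(p[mask] <= 0):
        return np.inf
    return -float(np.sum(d[mask] * np.log(p[mask])))


def fit_emt50(time: Sequence[float], emergence_pct: Sequence[float],
              n_at_risk: float, method: str = "binomial"
              ) -> tuple[float, float, dict]:
    """Fit the log-logistic emergence-time curve; return (EmT50, b, info).

    ``emergence_pct`` is the cumulative emergence of surviving individuals
    [%]; ``n_at_risk`` the number of individuals the percentages refer to.
    The default fit maximises the binomial likelihood of the per-interval
    emergence increments; ``method="ls"`` performs least squares on the
    cumulative curve instead (fallback for degenerate data).  ``info``
    carries the goodness of fit (R^2 on the cumulative scale) and a
    convergence flag.  By construction y(EmT50) = 0.5.
    """
    t = np.asarray(time, dtype=float)
    frac = np.asarray(emergence_pct, dtype=float) / 100.0
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not np.any((frac > 0) & (frac < 1)):
        raise ValueError("no emergence strictly between 0 and 100%")

    # moment start: time of median crossing, slope from the 25-75% span
    imed = int(np.argmax(frac >= 0.5)) if np.any(frac >= 0.5) else t.size - 1
    emt0 = t[imed]
    b0 = 10.0
    x0 = np.log([max(emt0, t[0]), b0])

    if method == "binomial":
        res = optimize.minimize(_binomial_nll, x0,
                                args=(t, np.clip(frac, 0.0, 1.0),
                                      float(n_at_risk)),
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        emt50, b = np.exp(res.x)
        converged = bool(res.success) and np.isfinite(res.fun)
        if not converged:
            warnings.warn("binomial log-logistic fit did not converge; "
                          "falling back to least squares", stacklevel=2)
            return fit_emt50(time, emergence_pct, n_at_risk, method="ls")
    elif method == "ls":
        def sse(theta):
            y = log_logistic(t, *np.exp(theta))
            return float(np.sum((y - frac) ** 2))
        res = optimize.minimize(sse, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12,
                                         "maxiter": 4000})
        emt50, b = np.exp(res.x)
        converged = bool(res.success)
    else:
        raise ValueError("method must be 'binomial' or 'ls'")

    yhat = log_logistic(t, emt50, b)
    ss_res = float(np.sum((frac - yhat) ** 2))
    ss_tot = float(np.sum((frac - frac.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return float(emt50), float(b), {"R2": r2, "converged": converged,
                                    "method": method}


def fit_mortality_power_law(densities: Sequence[float],
                            rates: Sequence[float],
                            fix_exponent: Optional[float] = None
                            ) -> tuple[float, float]:
    """Fit y = a x^b to (density, daily mortality rate) pairs.

    Ordinary least squares of log(rate) on log(density); non-positive
    rates are excluded with a warning.  With ``fix_exponent`` the exponent
    is held (e.g. at 0.4) and only ``a`` is estimated.  Returns (a, b).
    """
    x = np.asarray(densities, dtype=float)
    y = np.asarray(rates, dtype=float)
    keep = (x > 0) & (y > 0)
    if keep.sum() < x.size:
        warnings.warn(f"excluding {int(x.size - keep.sum())} non-positive "
                      "(density, rate) pairs from the power-law fit",
                      stacklevel=2)
    x, y = x[keep], y[keep]
    if x.size < (1 if fix_exponent is not None else 3):
        raise ValueError("not enough positive (density, rate) pairs")
    lx, ly = np.log(x), np.log(y)
    if fix_exponent is not None:
        return float(np.exp(np.mean(ly - fix_exponent * lx))), fix_exponent
    b, log_a = np.polyfit(lx, ly, 1)
    return float(np.exp(log_a)), float(b)


def endpoints_table(curves: pd.DataFrame,
                    duration_by: str = "last_day") -> pd.DataFrame:
    """Compute all endpoints for a tidy table of emergence curves.

    ``curves`` has one row per (scenario, replicate, day) with columns
    ``scenario, replicate, day, cumulative_emerged, n_initial`` and
    optionally ``n_dead_end`` (default: initial - emerged at the last day,
    i.e. no survivors).  Returns one row per (scenario, replicate) with
    the :class:`EndpointResult` fields.
    """
    required = {"scenario", "replicate", "day", "cumulative_emerged",
                "n_initial"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves table lacks columns {sorted(missing)}")
    out = []
    for (scen, rep), g in curves.groupby(["scenario", "replicate"],
                                         sort=False):
        g = g.sort_values("day")
        n0 = int(g["n_initial"].iloc[0])
        emerged_end = int(g["cumulative_emerged"].iloc[-1])
        if "n_dead_end" in g.columns:
            dead_end = int(g["n_dead_end"].iloc[0])
            survivors = n0 - emerged_end - dead_end
        else:
            dead_end = n0 - emerged_end
            survivors = 0
        duration = float(g["day"].iloc[-1])
        mort = total_mortality_pct(n0, emerged_end, survivors)
        rate = daily_mortality_rate(mort, duration)
        curve = EmergenceCurve(g["day"].to_numpy(),
                               g["cumulative_emerged"].to_numpy(),
                               n0, dead_end)
        row = {"scenario": scen, "replicate": rep,
               "total_mortality_pct": mort, "daily_mortality_rate": rate,
               "EmT50": np.nan, "slope_b": np.nan, "fit_R2": np.nan,
               "converged": False}
        try:
            pct = emergence_surv_pct(curve)
            emt50, b, info = fit_emt50(curve.time, pct, n0 - dead_end)
            row.update(EmT50=emt50, slope_b=b, fit_R2=info["R2"],
                       converged=info["converged"])
        except ValueError:
            pass  # degenerate curve (no emergence): endpoints stay NaN
        out.append(row)
    return pd.DataFrame(out)
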