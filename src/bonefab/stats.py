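"""Cohort-level statistics: descriptive summaries, power-law density-stiffness
fits and the one-parameter surface-fraction model fit.

The power-law model ``y = a * x**b`` is fitted by nonlinear least squares on
the original scale, initialized from the log-log linear fit; the surface model
``BS/TV = K * x * (1 - x)`` has a closed-form least-squares solution.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


@dataclass
class DescriptiveStats:
    """Mean, SD (n-1 denominator), CV%, median, min, max of a sample."""

    mean: float
    sd: float
    cv_percent: float
    median: float
    min: float
    max: float
    n: int
    degenerate: bool = False  # single observation: SD reported as 0

    def as_dict(self) -> dict:
        return asdict(self)


def describe(values: Sequence[float]) -> DescriptiveStats:
    """Descriptive statistics in the convention used for cohort tables."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("describe() needs at least one value")
    mean = float(v.mean())
    if v.size == 1:
        sd, degenerate = 0.0, True
    else:
        sd, degenerate = float(v.std(ddof=1)), False
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return DescriptiveStats(
        mean=mean,
        sd=sd,
        cv_percent=cv,
        median=float(np.median(v)),
        min=float(v.min()),
        max=float(v.max()),
        n=int(v.size),
        degenerate=degenerate,
    )


@dataclass
class PowerLawFit:
    """Least-squares fit of ``y = a * x**b`` with original-scale goodness of fit."""

    a: float
    b: float
    r_squared: float  # on the original scale
    r_squared_log: float  # on the log-log scale, for comparison
    p_value: float  # two-sided, from the t statistic of the log-log slope
    se_a: float
    se_b: float
    n: int
    residual_sd: float
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b

    def as_dict(self) -> dict:
        return asdict(self)


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Fit ``y = a * x**b`` by nonlinear least squares on the original scale.

    The fit is initialized from the ordinary linear regression of ``log y`` on
    ``log x``.  R^2 is ``1 - SS_res / SS_tot`` on the original scale (the
    log-scale value is reported alongside); the p-value is the two-sided test
    of zero log-log slope.  Constant ``y`` is returned as a flagged degenerate
    fit with ``b = 0`` rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"power-law fit needs n >= 3, got {n}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")

    lx, ly = np.log(x), np.log(y)
    lin = sps.linregress(lx, ly)
    if not np.isfinite(lin.slope) or np.allclose(ly, ly.mean()):
        a0, b0 = float(np.exp(ly.mean())), 0.0
    else:
        a0, b0 = float(np.exp(lin.intercept)), float(lin.slope)

    def model(xx, a, b):
        return a * xx**b

    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=(a0, b0), maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - pathological data
        raise RuntimeError(
            f"power-law fit did not converge (initializer a0={a0:.4g}, b0={b0:.4g})"
        ) from err
    a, b = float(popt[0]), float(popt[1])
    res = y - model(x, a, b)
    ss_res = float(res @ res)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    lres = ly - (np.log(a) + b * lx)
    lss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2_log = 1.0 - float(lres @ lres) / lss_tot if lss_tot > 0 else 0.0
    dof = max(n - 2, 1)
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    degenerate = ss_tot == 0.0 or abs(b) < 1e-12
    return PowerLawFit(
        a=a,
        b=b,
        r_squared=max(min(r2, 1.0), 0.0),
        r_squared_log=max(min(r2_log, 1.0), 0.0),
        p_value=float(lin.pvalue),
        se_a=float(se[0]),
        se_b=float(se[1]),
        n=n,
        residual_sd=float(np.sqrt(ss_res / dof)),
        degenerate=degenerate,
    )


def fit_surface_model(bv_tv: Sequence[float], bs_tv: Sequence[float]) -> tuple[float, float]:
    """Fit ``BS/TV = K * (BV/TV) * (1 - BV/TV)`` and return ``(K, R^2)``.

    The single parameter has the closed-form least-squares solution
    ``K = sum(w * y) / sum(w**2)`` with ``w = x * (1 - x)``.
    """
    x = np.asarray(bv_tv, dtype=float)
    y = np.asarray(bs_tv, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need matching 1-D arrays with n >= 2")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("BV/TV values must lie in [0, 1]")
    w = x * (1.0 - x)
    ww = float(w @ w)
    if ww == 0.0:
        raise ValueError("all BV/TV at 0 or 1: the regressor x(1-x) vanishes")
    k = float(w @ y) / ww
    res = y - k * w
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(res @ res) / ss_tot if ss_tot > 0 else 0.0
    return k, r2


def group_summaries(
    table: pd.DataFrame,
    by: str,
    value_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-group :func:`describe` of each value column, keyed by a tag column.

    ``by`` is typically ``level`` (L1-L5), ``region`` (ac/pc/pl/pr) or
    ``donor``.  Returns a tidy frame with one row per (group, variable).
    """
    if by not in table.columns:
        raise KeyError(f"unknown grouping column {by!r}; have {list(table.columns)}")
    if value_columns is None:
        value_columns = [
            c for c in table.columns if c != by and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for key, grp in table.groupby(by, sort=True):
        for col in value_columns:
            vals = grp[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            d = describe(vals)
            rows.append({by: key, "variable": col, **d.as_dict()})
    return pd.DataFrame(rows)


def cohort_descriptives(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Whole-cohort mean/SD/CV/median/min/max for the listed columns."""
    rows = []
    for col in columns:
        if col not in table.columns:
            continue
        vals = table[col].dropna().to_numpy()
        if vals.size == 0:
            continue
        rows.append({"variable": col, **describe(vals).as_dict()})
    return pd.DataFrame(rows)
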