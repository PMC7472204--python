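"""Validation statistics and vegetation-index correlation fits.

Bias uses the simulated value as reference, Bias = (yhat - y)/yhat; RMSE is
the usual root-mean-square difference of paired series.  Correlation fits are
ordinary least squares of y on x (linear) or on ln x (logarithmic), reported
with the coefficient of determination R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = ["FitReport", "bias", "rmse", "fit", "fit_table"]


@dataclass(frozen=True)
class FitReport:
    """y = a*x + b (model='linear') or y = a*ln(x) + b (model='log'), with R^2."""

    model: str
    a: float
    b: float
    r2: float

    def __post_init__(self):
        if self.model not in ("linear", "log"):
            raise ValueError("model must be 'linear' or 'log'")
        if not np.isfinite([self.a, self.b, self.r2]).all():
            raise ValueError("non-finite fit coefficients")
        if not -1e-12 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"R^2 = {self.r2} outside [0, 1]")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        t = np.log(x) if self.model == "log" else x
        return self.a * t + self.b

    def equation(self) -> str:
        term = "ln(x)" if self.model == "log" else "x"
        sign = "+" if self.b >= 0 else "-"
        return f"y = {self.a:.4g}{term} {sign} {abs(self.b):.4g}"


def bias(simulated: float, measured: float) -> float:
    """Signed relative deviation (yhat - y)/yhat with the simulated value as reference."""
    if simulated == 0.0:
        raise ZeroDivisionError("simulated reference value is zero; bias undefined")
    return (simulated - measured) / simulated


def rmse(simulated, measured) -> float:
    """Root-mean-square error between paired series."""
    s = np.asarray(simulated, float)
    m = np.asarray(measured, float)
    if s.shape != m.shape:
        raise ValueError("series length mismatch")
    if s.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean((s - m) ** 2)))


def fit(x, y, model: str = "linear") -> FitReport:
    """OLS fit of y against x (or ln x); requires n >= 3 and non-degenerate data."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if model == "log":
        if np.any(x <= 0):
            raise ValueError("log model requires x > 0")
        t = np.log(x)
    elif model == "linear":
        t = x
    else:
        raise ValueError("model must be 'linear' or 'log'")
    if np.ptp(t) == 0.0:
        raise ValueError("zero variance in x; fit undefined")
    if np.ptp(y) == 0.0:
        raise ValueError("zero variance in y; R^2 undefined")
    res = _stats.linregress(t, y)
    return FitReport(model=model, a=float(res.slope), b=float(res.intercept), r2=float(res.rvalue**2))


def fit_table(rows: list[tuple[str, str, FitReport]]) -> pd.DataFrame:
    """Report table: (agronomic parameter, vegetation index, fit) triples."""
    return pd.DataFrame(
        {
            "parameter": [p for p, _, _ in rows],
            "vegetation_index": [v for _, v, _ in rows],
            "model": [f.model for _, _, f in rows],
            "equation": [f.equation() for _, _, f in rows],
            "a": [f.a for _, _, f in rows],
            "b": [f.b for _, _, f in rows],
            "r2": [f.r2 for _, _, f in rows],
        }
    )
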