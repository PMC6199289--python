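"""Structure-to-function calibration: predicting force from image morphometry.

The calibration is a per-pair simple linear regression between one
morphometric order parameter (CAS, VD, stretch-corrected VD, or SL) and one
mechanical outcome (pCa50, maximum force per diameter, specific force, or
maximum stress), quantified by the Pearson correlation.  Groups such as
healthy-like and dystrophic-like fibers are carried as labels and pooled:
the calibration exploits the widened dynamic range of pooled cohorts.

The Pearson p-value is computed from the exact t-transform
t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom, and predictions
carry the standard linear-model prediction interval, so force can be
predicted from an image-derived order parameter with quantified
uncertainty.  No multiple-testing correction is applied across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationPair",
    "CalibrationModel",
    "pearson",
    "fit_calibration",
    "predict_force",
    "fit_combined_predictor",
]

X_NAMES = ("cas", "vd", "vd_corrected", "sl_um")
Y_NAMES = ("pca50", "max_force_per_diameter", "specific_force", "max_stress")


@dataclass
class CalibrationPair:
    """Per-fiber records pairing a structural and a functional variable."""

    x_name: str
    y_name: str
    records: pd.DataFrame  # columns: fiber_id, group, x, y

    def __post_init__(self) -> None:
        if self.x_name not in X_NAMES:
            raise ValueError(f"x_name must be one of {X_NAMES}")
        if self.y_name not in Y_NAMES:
            raise ValueError(f"y_name must be one of {Y_NAMES}")
        req = {"fiber_id", "group", "x", "y"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(req)}")
        xy = self.records[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("x and y must be finite")
        if len(self.records) < 3:
            raise ValueError("need at least 3 records")


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Product-moment correlation with its exact two-sided p-value.

    r is computed from the centred cross- and auto-moments; the p-value
    uses the t-transform t = r*sqrt((n-2)/(1-r^2)) referred to a
    t-distribution with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need matched samples with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.dot(xc, yc) / np.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


@dataclass
class CalibrationModel:
    """Fitted linear structure-to-function relation with its uncertainty."""

    x_name: str
    y_name: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float
    x_range: tuple[float, float]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("|r| must be <= 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")
        if self.slope != 0 and np.sign(self.slope) != np.sign(self.pearson_r):
            raise ValueError("slope and r must share a sign")

    def prediction_halfwidth(self, x: float, level: float = 0.95) -> float:
        """Half-width of the prediction interval for a new observation at x."""
        if self.n <= 2:
            return float("inf")
        tcrit = stats.t.ppf(0.5 + level / 2.0, df=self.n - 2)
        se = self.residual_sd * np.sqrt(
            1.0 + 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )
        return float(tcrit * se)

    def predict(self, x: float, level: float = 0.95) -> tuple[float, tuple[float, float], bool]:
        """Point prediction with interval; the flag marks extrapolation."""
        lo, hi = self.x_range
        span = hi - lo
        extrapolated = not (lo - 0.5 * span <= x <= hi + 0.5 * span)
        point = self.slope * x + self.intercept
        hw = self.prediction_halfwidth(x, level)
        return float(point), (float(point - hw), float(point + hw)), extrapolated

    def summary(self) -> str:
        lines = [
            f"Calibration {self.x_name} -> {self.y_name}",
            "-----------------------------------",
            f"slope        {self.slope:10.4f}",
            f"intercept    {self.intercept:10.4f}",
            f"Pearson r    {self.pearson_r:10.4f}",
            f"p (2-sided)  {self.p_value:10.3g}",
            f"n fibers     {self.n:10d}",
            f"residual SD  {self.residual_sd:10.4f}",
        ]
        return "\n".join(lines)


def fit_calibration(pair: CalibrationPair) -> CalibrationModel:
    """Ordinary least-squares line through the paired records."""
    x = pair.records["x"].to_numpy(dtype=float)
    y = pair.records["y"].to_numpy(dtype=float)
    r, p, n = pearson(x, y)
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    slope = float(np.dot(xc, y - y.mean()) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    dof = n - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return CalibrationModel(
        x_name=pair.x_name,
        y_name=pair.y_name,
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        p_value=p,
        n=n,
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        sxx=sxx,
        x_range=(float(x.min()), float(x.max())),
        groups=sorted(set(pair.records["group"].astype(str))),
    )


def predict_force(
    model: CalibrationModel, x: float, level: float = 0.95
) -> tuple[float, tuple[float, float], bool]:
    """Predict the functional variable from a morphometric value.

    Returns (point, (lower, upper), extrapolation_flag); the interval is a
    prediction interval for a single new fiber at the requested level.
    """
    if model is None:
        raise ValueError("model must be fitted first")
    return model.predict(x, level)


def fit_combined_predictor(
    records: pd.DataFrame, x_names: Sequence[str] = ("cas", "vd"), y_name: str = "pca50"
) -> dict:
    """Multivariate OLS over several order parameters at once.

    Extension beyond the per-pair calibration design: a single linear
    predictor ``y ~ 1 + x1 + x2 + ...`` fitted by least squares. Returns
    the coefficient dict, residual SD and R^2. Use when the univariate
    calibrations leave structure on the table; interpret with care, since
    CAS and VD are themselves correlated.
    """
    cols = list(x_names) + [y_name]
    sub = records[cols].dropna()
    if len(sub) < len(x_names) + 2:
        raise ValueError("not enough records for the multivariate fit")
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(float) for c in x_names])
    y = sub[y_name].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(sub) - X.shape[1]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return {
        "intercept": float(beta[0]),
        "coefficients": {n: float(b) for n, b in zip(x_names, beta[1:])},
        "residual_sd": float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0,
        "r_squared": 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0,
        "n": int(len(sub)),
    }
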