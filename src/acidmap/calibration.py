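"""Ratiometric pH calibration models.

The classical route to pH: ordinary least squares of the peak-intensity
ratio on pH over buffer standards, ``ratio = slope * pH + intercept``,
inverted algebraically at prediction time, ``pH = (ratio - intercept) /
slope``. A quadratic inverse-regression comparator (pH fitted directly as a
degree-2 polynomial of the ratio) is provided as the conventional nonlinear
baseline the learned model is compared against.

Both follow the model/results idiom: construct a model from data, call
``fit()``, get a results object carrying estimates, uncertainties and a
``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import statsmodels.api as sm

__all__ = [
    "RatiometricCalibration",
    "CalibrationResults",
    "QuadraticInversion",
    "QuadraticInversionResults",
    "fit_calibration",
    "predict_ph_ratiometric",
    "load_calibration",
]


class RatiometricCalibration:
    """OLS model of peak ratio on pH over calibration standards.

    Parameters
    ----------
    ph : array-like
        pH of each calibration standard. At least 3 distinct values.
    ratio : array-like
        Measured peak2/peak1 intensity ratio for each standard.
    """

    def __init__(self, ph, ratio):
        self.ph = np.asarray(ph, dtype=float)
        self.ratio = np.asarray(ratio, dtype=float)
        if self.ph.shape != self.ratio.shape or self.ph.ndim != 1:
            raise ValueError("ph and ratio must be 1-D arrays of equal length")
        if np.unique(self.ph).size < 2:
            raise ValueError("all pH values identical: degenerate design")
        if np.unique(self.ph).size < 3 and self.ph.size < 3:
            # two distinct points are allowed (fit is exact) but fewer are not
            if self.ph.size < 2:
                raise ValueError("need at least 2 calibration points")

    @classmethod
    def from_dataframe(cls, frame, ph_col: str = "ph", ratio_col: str = "ratio"):
        return cls(frame[ph_col].to_numpy(), frame[ratio_col].to_numpy())

    def fit(self) -> "CalibrationResults":
        exog = sm.add_constant(self.ph)
        with np.errstate(divide="ignore"):  # 2-point fits have df_resid = 0
            res = sm.OLS(self.ratio, exog).fit()
        intercept, slope = res.params
        return CalibrationResults(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(res.rsquared) if self.ph.size > 2 else 1.0,
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            ph_domain=(float(self.ph.min()), float(self.ph.max())),
            nobs=int(self.ph.size),
        )


@dataclass
class CalibrationResults:
    """Fitted calibration line and its inverse pH predictor."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    ph_domain: tuple[float, float]
    nobs: int
    preprocessing_options: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")

    def predict_ratio(self, ph) -> np.ndarray:
        """Forward model: expected ratio at ``ph``."""
        return self.slope * np.asarray(ph, dtype=float) + self.intercept

    def predict_ph(self, ratio) -> tuple[np.ndarray, np.ndarray]:
        """Invert the line: ``pH = (ratio - intercept) / slope``.

        Returns ``(ph, in_domain)`` where ``in_domain`` flags predictions
        inside the calibrated pH range. Out-of-domain values are flagged,
        never clamped — clamping is a rendering concern only.
        """
        ratio = np.asarray(ratio, dtype=float)
        ph = (ratio - self.intercept) / self.slope
        lo, hi = self.ph_domain
        in_domain = (ph >= lo) & (ph <= hi)
        return ph, in_domain

    def summary(self) -> str:
        lo, hi = self.ph_domain
        lines = [
            "Ratiometric pH calibration (OLS: ratio ~ pH)",
            "=" * 46,
            f"n points            {self.nobs:>10d}",
            f"slope               {self.slope:>12.4f}  (SE {self.slope_se:.2e})",
            f"intercept           {self.intercept:>12.4f}  (SE {self.intercept_se:.2e})",
            f"R-squared           {self.r_squared:>12.4f}",
            f"pH domain           [{lo:.2f}, {hi:.2f}]",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "ph_domain": list(self.ph_domain),
            "nobs": self.nobs,
            "created": datetime.now(timezone.utc).isoformat(),
            "preprocessing_options": self.preprocessing_options,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def load_calibration(path: str | Path) -> CalibrationResults:
    data = json.loads(Path(path).read_text())
    return CalibrationResults(
        slope=data["slope"],
        intercept=data["intercept"],
        r_squared=data["r_squared"],
        slope_se=data.get("slope_se", float("nan")),
        intercept_se=data.get("intercept_se", float("nan")),
        ph_domain=tuple(data["ph_domain"]),
        nobs=data.get("nobs", 0),
        preprocessing_options=data.get("preprocessing_options"),
    )


def fit_calibration(points) -> CalibrationResults:
    """Fit the calibration line from ``(ph, ratio)`` pairs.

    Requires at least 3 points with at least 2 distinct pH values (two
    points give an exact fit with R-squared 1 by construction).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (ph, ratio) pairs")
    return RatiometricCalibration(pts[:, 0], pts[:, 1]).fit()


def predict_ph_ratiometric(ratio, model: CalibrationResults):
    """Functional form of :meth:`CalibrationResults.predict_ph`.

    Scalar in, scalar out (with the out-of-domain flag); array in, arrays
    out.
    """
    ratio_arr = np.asarray(ratio, dtype=float)
    ph, in_domain = model.predict_ph(ratio_arr)
    if np.isscalar(ratio) or ratio_arr.ndim == 0:
        return float(ph), bool(in_domain)
    return ph, in_domain


class QuadraticInversion:
    """Conventional nonlinear comparator: pH as a quadratic in the ratio.

    Fits ``pH = a * ratio^2 + b * ratio + c`` by least squares — the
    lowest-complexity nonlinear inverse regression. It nests every linear
    predictor of pH from the ratio, so its in-sample SSE can never exceed
    the inverted calibration line's.
    """

    def __init__(self, ph, ratio):
        self.ph = np.asarray(ph, dtype=float)
        self.ratio = np.asarray(ratio, dtype=float)
        if self.ph.shape != self.ratio.shape or self.ph.ndim != 1:
            raise ValueError("ph and ratio must be 1-D arrays of equal length")
        if self.ph.size < 4:
            raise ValueError("need at least 4 points for the quadratic comparator")

    def fit(self) -> "QuadraticInversionResults":
        design = np.column_stack(
            [np.ones_like(self.ratio), self.ratio, self.ratio**2]
        )
        if np.linalg.matrix_rank(design) < 3:
            raise ValueError(
                "rank-deficient design (ratios do not span a quadratic); "
                "cannot fit the comparator"
            )
        res = sm.OLS(self.ph, design).fit()
        return QuadraticInversionResults(
            coefficients=tuple(float(c) for c in res.params),
            r_squared=float(res.rsquared),
            nobs=int(self.ph.size),
        )


@dataclass
class QuadraticInversionResults:
    coefficients: tuple[float, float, float]  # (c, b, a) for c + b*r + a*r^2
    r_squared: float
    nobs: int

    def predict_ph(self, ratio) -> tuple[np.ndarray, np.ndarray]:
        """Same predict interface as the calibration line (flag always in
        domain: the quadratic has no calibrated domain of its own)."""
        r = np.asarray(ratio, dtype=float)
        c, b, a = self.coefficients
        ph = c + b * r + a * r * r
        return ph, np.ones_like(ph, dtype=bool)

    def summary(self) -> str:
        c, b, a = self.coefficients
        return "\n".join(
            [
                "Quadratic inverse regression (pH ~ ratio + ratio^2)",
                "=" * 51,
                f"n points            {self.nobs:>10d}",
                f"pH = {a:+.5g} * r^2 {b:+.5g} * r {c:+.5g}",
                f"R-squared           {self.r_squared:>12.4f}",
            ]
        )
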