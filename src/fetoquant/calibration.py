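"""Spiked-standard calibration: replicate aggregation, CV gating, the
prohibited low-amount margin, and the log10-log10 regression used to map
normalized intensities to absolute concentrations.

The quality gates mirror standard dilution-ladder practice: a calibration
point is kept only if it was detected in at least two technical replicates,
its replicate CV (sample SD / mean) does not exceed 20% (10% at the top
concentration, 500 fmol/uL by default), and its on-column amount falls
outside the prohibited margin [0.5, 42) fmol where the response is
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ComputationError, InsufficientCalibrationError, ValidationError

CV_MAX = 0.20
CV_MAX_TOP = 0.10
TOP_CONC_FMOL_UL = 500.0
PROHIBITED_MARGIN_FMOL = (0.5, 42.0)
INJECTION_UL = 2.0

REJECTION_REASONS = ("none", "cv_fail", "top_cv_fail", "margin", "undetected")


@dataclass
class CalibrationPoint:
    """One protein's aggregated calibration measurement."""

    protein_id: str
    nominal_conc_fmol_ul: float
    replicate_intensities: list[float]
    mean_intensity: float = float("nan")
    cv: float = float("nan")
    selected: bool = False
    rejection_reason: str = "none"

    def reject(self, reason: str) -> None:
        assert reason in REJECTION_REASONS
        self.selected = False
        self.rejection_reason = reason


def aggregate_replicates(replicates: pd.DataFrame) -> list[CalibrationPoint]:
    """Aggregate a replicate intensity table into calibration points.

    Expects columns protein_id, nominal_conc_fmol_ul, intensity (one row per
    detected replicate). Points with fewer than two detected replicates are
    marked ``undetected``; others get mean and relative SD (sample SD, ddof=1,
    divided by the mean).
    """
    points = []
    for (pid, conc), grp in replicates.groupby(
        ["protein_id", "nominal_conc_fmol_ul"], sort=True
    ):
        vals = grp["intensity"].to_numpy(dtype=float)
        pt = CalibrationPoint(pid, float(conc), vals.tolist())
        if len(vals) < 2:
            pt.reject("undetected")
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            if mean == 0:
                if sd > 0:
                    raise ComputationError(
                        f"{pid}: zero mean with nonzero SD, CV undefined")
                pt.mean_intensity, pt.cv = 0.0, 0.0
                pt.selected = True
            else:
                pt.mean_intensity = mean
                pt.cv = sd / mean
                pt.selected = True
        points.append(pt)
    return points


def cv_filter(
    points: Sequence[CalibrationPoint],
    cv_max: float = CV_MAX,
    cv_max_top: float = CV_MAX_TOP,
    top_conc: float = TOP_CONC_FMOL_UL,
) -> list[CalibrationPoint]:
    """Reject points whose replicate CV exceeds the gate (tighter at the top
    concentration). Idempotent; already-rejected points are left untouched."""
    if not 0 < cv_max_top <= cv_max:
        raise ValidationError("need 0 < cv_max_top <= cv_max")
    for pt in points:
        if not pt.selected:
            continue
        if pt.nominal_conc_fmol_ul == top_conc and pt.cv > cv_max_top:
            pt.reject("top_cv_fail")
        elif pt.cv > cv_max:
            pt.reject("cv_fail")
    return list(points)


def apply_prohibited_margin(
    points: Sequence[CalibrationPoint],
    margin_fmol: tuple[float, float] = PROHIBITED_MARGIN_FMOL,
    injection_ul: float = INJECTION_UL,
) -> list[CalibrationPoint]:
    """Reject points whose on-column amount (concentration x injection
    volume) lies inside the half-open prohibited band [low, high) fmol."""
    low, high = margin_fmol
    if not low < high:
        raise ValidationError("margin low must be < high")
    if injection_ul <= 0:
        raise ValidationError("injection volume must be > 0")
    for pt in points:
        if not pt.selected:
            continue
        on_column = pt.nominal_conc_fmol_ul * injection_ul
        if low <= on_column < high:
            pt.reject("margin")
    return list(points)


class LogLogCalibration(BaseEstimator):
    """Ordinary least squares of log10(intensity) on log10(concentration),
    with gated point selection and flagged inverse prediction.

    Follows the scikit-learn estimator protocol: hyperparameters are
    constructor arguments, ``fit`` learns ``slope_``, ``intercept_``
    (log10 intensity at 1 fmol/uL), ``r_squared_``, ``valid_range_`` (the
    span of selected nominal concentrations) and ``n_points_``;
    ``predict`` maps intensities back to concentrations.

    Parameters
    ----------
    cv_max, cv_max_top, top_conc : replicate-CV gates.
    margin_fmol : half-open prohibited on-column band [low, high) in fmol.
    injection_ul : injection volume mapping fmol/uL to on-column fmol.
    """

    def __init__(
        self,
        cv_max: float = CV_MAX,
        cv_max_top: float = CV_MAX_TOP,
        top_conc: float = TOP_CONC_FMOL_UL,
        margin_fmol: tuple[float, float] = PROHIBITED_MARGIN_FMOL,
        injection_ul: float = INJECTION_UL,
    ):
        self.cv_max = cv_max
        self.cv_max_top = cv_max_top
        self.top_conc = top_conc
        self.margin_fmol = margin_fmol
        self.injection_ul = injection_ul

    # -- fitting ------------------------------------------------------------

    def fit(self, replicates: pd.DataFrame, y=None) -> "LogLogCalibration":
        """Aggregate, gate and regress a replicate intensity table."""
        points = aggregate_replicates(replicates)
        cv_filter(points, self.cv_max, self.cv_max_top, self.top_conc)
        apply_prohibited_margin(points, tuple(self.margin_fmol),
                                self.injection_ul)
        return self.fit_points(points)

    def fit_points(
        self, points: Sequence[CalibrationPoint]
    ) -> "LogLogCalibration":
        """Fit the regression on the already-gated selected points."""
        selected = [p for p in points if p.selected]
        if len(selected) < 3:
            raise InsufficientCalibrationError(
                f"only {len(selected)} selected calibration points (need >= 3)"
            )
        x = np.log10([p.nominal_conc_fmol_ul for p in selected])
        if np.ptp(x) < 1e-12:
            raise ComputationError("zero variance in calibration "
                                   "concentrations; cannot regress")
        y = np.log10([p.mean_intensity for p in selected])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r_squared_ = (1.0 - float(np.sum(resid ** 2)) / ss_tot
                           if ss_tot > 0 else 1.0)
        self.valid_range_ = (
            float(min(p.nominal_conc_fmol_ul for p in selected)),
            float(max(p.nominal_conc_fmol_ul for p in selected)),
        )
        self.n_points_ = len(selected)
        self.points_ = list(points)
        return self

    # -- prediction ---------------------------------------------------------

    def predict(self, intensity, return_flags: bool = False):
        """Invert the curve: concentration = 10**((log10 I - b) / a).

        With ``return_flags=True`` also returns, per value, the set of
        applicable flags: ``extrapolated`` (outside the fitted validity
        range) and ``unreliable_margin`` (on-column amount inside the
        prohibited band).
        """
        self._check_fitted()
        if self.slope_ == 0:
            raise ComputationError("zero slope: calibration not invertible")
        arr = np.atleast_1d(np.asarray(intensity, dtype=float))
        if np.any(arr <= 0):
            raise ValidationError("intensity must be > 0 to predict")
        conc = 10.0 ** ((np.log10(arr) - self.intercept_) / self.slope_)
        if not return_flags:
            return conc if np.ndim(intensity) else float(conc[0])
        low, high = self.valid_range_
        mlow, mhigh = self.margin_fmol
        flags = []
        for c in conc:
            f = set()
            if not low <= c <= high:
                f.add("extrapolated")
            if mlow <= c * self.injection_ul < mhigh:
                f.add("unreliable_margin")
            flags.append(f)
        if np.ndim(intensity):
            return conc, flags
        return float(conc[0]), flags[0]

    def predict_intensity(self, conc) -> np.ndarray | float:
        """Forward direction: fitted intensity at a given concentration."""
        self._check_fitted()
        arr = np.asarray(conc, dtype=float)
        out = 10.0 ** (self.intercept_ + self.slope_ * np.log10(arr))
        return out if arr.ndim else float(out)

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise ComputationError("calibration curve is not fitted")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "slope": self.slope_,
            "intercept": self.intercept_,
            "r_squared": self.r_squared_,
            "valid_range_fmol_ul": list(self.valid_range_),
            "n_points": self.n_points_,
            "cv_max": self.cv_max,
            "cv_max_top": self.cv_max_top,
            "top_conc": self.top_conc,
            "prohibited_margin_fmol": list(self.margin_fmol),
            "injection_ul": self.injection_ul,
            "points": [
                {
                    "protein_id": p.protein_id,
                    "nominal_conc_fmol_ul": p.nominal_conc_fmol_ul,
                    "mean_intensity": p.mean_intensity,
                    "cv": p.cv,
                    "selected": p.selected,
                    "rejection_reason": p.rejection_reason,
                }
                for p in getattr(self, "points_", [])
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogLogCalibration":
        model = cls(
            cv_max=d["cv_max"],
            cv_max_top=d["cv_max_top"],
            top_conc=d["top_conc"],
            margin_fmol=tuple(d["prohibited_margin_fmol"]),
            injection_ul=d["injection_ul"],
        )
        model.slope_ = d["slope"]
        model.intercept_ = d["intercept"]
        model.r_squared_ = d["r_squared"]
        model.valid_range_ = tuple(d["valid_range_fmol_ul"])
        model.n_points_ = d["n_points"]
        model.points_ = [
            CalibrationPoint(
                protein_id=p["protein_id"],
                nominal_conc_fmol_ul=p["nominal_conc_fmol_ul"],
                replicate_intensities=[],
                mean_intensity=p["mean_intensity"],
                cv=p["cv"],
                selected=p["selected"],
                rejection_reason=p["rejection_reason"],
            )
            for p in d.get("points", [])
        ]
        return model


# -- thin functional wrappers (the estimator is the implementation) ---------

def fit_loglog(points: Sequence[CalibrationPoint],
               **params) -> LogLogCalibration:
    """Fit the log-log regression on pre-gated points."""
    return LogLogCalibration(**params).fit_points(points)


def predict_concentration(curve: LogLogCalibration, intensity):
    """Map a normalized intensity to (concentration, flags)."""
    return curve.predict(intensity, return_flags=True)


def calibrate(replicates: pd.DataFrame, **params) -> LogLogCalibration:
    """One-call pipeline: aggregate -> CV gates -> margin gate -> regression."""
    return LogLogCalibration(**params).fit(replicates)


def rejection_tally(points: Sequence[CalibrationPoint]) -> dict[str, int]:
    tally: dict[str, int] = {r: 0 for r in REJECTION_REASONS}
    for p in points:
        tally["none" if p.selected else p.rejection_reason] += 1
    return tally
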