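"""Two-stage fluorescence-to-protein-mass calibration and yield arithmetic.

Stage 1 maps densitometry signal to protein mass via purified standards
(valid 70-500 ng by default); stage 2 maps plate-reader RFU to mass via
experimental samples whose signals were converted through stage 1. Both
stages are straight-line OLS fits (optionally through the origin) and both
predict by inversion of the forward regression, so exactly linear inputs
round-trip exactly. Predictions outside the standards' range are flagged,
not refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationError",
    "LinearStage",
    "CalibrationCurve",
    "MassEstimate",
    "fit_calibration",
    "rfu_to_mass",
    "lane_fraction",
]

DEFAULT_STANDARD_RANGE_NG = (70.0, 500.0)


class CalibrationError(ValueError):
    """Calibration could not be fitted (too few points, nonpositive slope)."""


@dataclass(frozen=True)
class LinearStage:
    """One forward regression ``signal = slope * ng + intercept``."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float

    def invert(self, signal) -> np.ndarray:
        """Predict ng from signal by inverting the forward line."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class CalibrationCurve:
    stage1: LinearStage  # blot signal vs ng standard
    stage2: LinearStage  # RFU vs ng (samples, via stage1)
    valid_range: tuple[float, float]  # ng

    @property
    def ng_per_rfu(self) -> float:
        """Inverse stage-2 slope: mass per fluorescence unit."""
        return 1.0 / self.stage2.slope


@dataclass(frozen=True)
class MassEstimate:
    ng_protein: float
    mg_per_l: float
    extrapolated: bool
    clipped: bool = False


def _ols_line(x: np.ndarray, y: np.ndarray, through_origin: bool) -> LinearStage:
    if through_origin:
        denom = float(np.dot(x, x))
        slope = float(np.dot(x, y)) / denom
        resid = y - slope * x
        dof = max(x.size - 1, 1)
        se = float(np.sqrt(np.sum(resid**2) / dof / denom))
        return LinearStage(slope=slope, intercept=0.0, slope_se=se, intercept_se=0.0)
    res = stats.linregress(x, y)
    return LinearStage(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr) if np.isfinite(res.stderr) else np.nan,
        intercept_se=float(res.intercept_stderr)
        if np.isfinite(res.intercept_stderr)
        else np.nan,
    )


def fit_calibration(
    standards: tuple[np.ndarray, np.ndarray],
    samples: tuple[np.ndarray, np.ndarray],
    through_origin: bool = False,
    valid_range: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Fit both calibration stages.

    Parameters
    ----------
    standards : (ng, signal)
        Purified-protein standards: known mass and measured blot signal.
    samples : (rfu, signal)
        Experimental samples measured on both instruments; their signals
        are converted to ng through stage 1 before fitting stage 2.
    valid_range : (ng, ng), optional
        Calibrated interval; defaults to the span of the standards.
    """
    ng = np.asarray(standards[0], dtype=float)
    sig = np.asarray(standards[1], dtype=float)
    rfu = np.asarray(samples[0], dtype=float)
    ssig = np.asarray(samples[1], dtype=float)
    if ng.size < 3 or rfu.size < 3:
        raise CalibrationError("each calibration stage needs >= 3 points")
    stage1 = _ols_line(ng, sig, through_origin)
    if stage1.slope <= 0:
        raise CalibrationError("stage-1 slope must be positive")
    sample_ng = stage1.invert(ssig)
    stage2 = _ols_line(sample_ng, rfu, through_origin)
    if stage2.slope <= 0:
        raise CalibrationError("stage-2 slope must be positive")
    if valid_range is None:
        valid_range = (float(np.min(ng)), float(np.max(ng)))
    return CalibrationCurve(stage1=stage1, stage2=stage2, valid_range=valid_range)


def rfu_to_mass(
    rfu: float, cal: CalibrationCurve, culture_volume_ml: float = 1.0
) -> MassEstimate:
    """Convert a fluorescence reading to protein mass and volumetric yield.

    ``mg_per_l = ng / culture_volume_ml / 1000`` (1000 ng/ml = 1 mg/l).
    Negative predictions are clipped to zero and flagged; predictions
    outside the calibrated ng range carry an ``extrapolated`` flag.
    """
    if culture_volume_ml <= 0:
        raise ValueError("culture volume must be positive")
    ng = float(cal.stage2.invert(rfu))
    clipped = ng < 0
    ng = max(ng, 0.0)
    extrapolated = not (cal.valid_range[0] <= ng <= cal.valid_range[1])
    return MassEstimate(
        ng_protein=ng,
        mg_per_l=ng / culture_volume_ml / 1000.0,
        extrapolated=extrapolated,
        clipped=clipped,
    )


def lane_fraction(band_intensity: float, total_lane_intensity: float) -> float:
    """Densitometry band fraction as % of total lane intensity."""
    if total_lane_intensity <= 0:
        raise ValueError("total lane intensity must be positive")
    if band_intensity < 0 or band_intensity > total_lane_intensity:
        raise ValueError("band intensity must lie in [0, total]")
    return 100.0 * band_intensity / total_lane_intensity
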