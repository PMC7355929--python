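"""Targeted method-performance statistics for standard-addition calibration.

Responses are internal-standard normalized: the neat (unspiked) sample
peak area is subtracted from the spiked peak area and the difference is
divided by the IS peak area.  Calibration is ordinary least squares of
response on spiked concentration (mg/kg); detection limits come from the
standard error of the intercept Sa and the slope b::

    LOD = 3.3 Sa / b        LOQ = 10 Sa / b

so LOQ / LOD = 10 / 3.3 identically.  Recovery is 100 * measured / spiked;
the matrix effect is the signed slope ratio 100 * (b_matrix / b_solvent - 1)
(negative = suppression); precision is the percent relative standard
deviation of replicates (intra-day) or of the pooled two-day replicates
(inter-day).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "normalized_response",
    "fit_calibration",
    "lod",
    "loq",
    "recovery",
    "matrix_effect",
    "precision",
]


def normalized_response(spiked_area: float, neat_area: float,
                        is_area: float) -> float:
    """IS-normalized standard-addition response; may be negative at levels
    near the noise floor."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    return (spiked_area - neat_area) / is_area


@dataclass
class CalibrationCurve:
    """OLS line response = a + b * level with standard errors and r^2."""

    analyte: str
    levels: np.ndarray
    responses: np.ndarray
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float


def fit_calibration(levels, responses, analyte: str = "") -> CalibrationCurve:
    """Ordinary least squares calibration fit (>= 3 distinct levels)."""
    levels = np.asarray(levels, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if levels.shape != responses.shape:
        raise ValueError("levels and responses differ in length")
    if len(np.unique(levels)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    if np.ptp(responses) == 0:
        # flat response: zero slope, zero residuals, no explainable variance
        return CalibrationCurve(
            analyte=analyte, levels=levels, responses=responses,
            slope=0.0, slope_se=0.0,
            intercept=float(responses[0]), intercept_se=0.0, r2=0.0,
        )
    res = stats.linregress(levels, responses)
    return CalibrationCurve(
        analyte=analyte,
        levels=levels,
        responses=responses,
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        r2=float(res.rvalue ** 2),
    )


def lod(curve: CalibrationCurve) -> float:
    """Limit of detection, 3.3 Sa / b, in concentration units."""
    if curve.slope == 0:
        raise ValueError("zero slope")
    return 3.3 * curve.intercept_se / abs(curve.slope)


def loq(curve: CalibrationCurve) -> float:
    """Limit of quantification, 10 Sa / b, in concentration units."""
    if curve.slope == 0:
        raise ValueError("zero slope")
    return 10.0 * curve.intercept_se / abs(curve.slope)


def recovery(measured: float, spiked: float) -> float:
    """Relative recovery in percent."""
    if spiked <= 0:
        raise ValueError("spiked concentration must be positive")
    return 100.0 * measured / spiked


def matrix_effect(slope_matrix: float, slope_solvent: float) -> float:
    """Signed matrix effect in percent from the slope ratio; suppression
    is negative."""
    if slope_solvent == 0:
        raise ValueError("zero solvent-curve slope")
    return 100.0 * (slope_matrix / slope_solvent - 1.0)


def precision(replicates, day: np.ndarray | None = None) -> float:
    """Percent relative standard deviation of replicate values.

    Intra-day: pass the replicate values directly.  Inter-day: pass all
    replicates with a ``day`` array; both days' replicates are pooled into
    one RSD (n x k design).
    """
    values = np.asarray(replicates, dtype=float)
    if day is not None:
        if len(day) != len(values):
            raise ValueError("day labels do not match replicates")
        # pooling is the definition used for the n x k reproducibility RSD
    if len(values) < 2:
        raise ValueError("need at least 2 replicates")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("non-positive mean is non-physical for peak areas")
    return 100.0 * values.std(ddof=1) / mean
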