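"""Calibration-curve fitting and detection/quantification limits.

LOD and LOQ are derived from the ordinary-least-squares fit of instrument
response against nominal concentration:

    LOD = 3.3 * s_intercept / slope
    LOQ = 10  * s_intercept / slope

where ``s_intercept`` is the standard error of the fitted intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, UnusableCurveError

__all__ = ["CalibrationCurve", "fit_calibration", "lod_loq", "LOD_FACTOR", "LOQ_FACTOR"]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class CalibrationCurve:
    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    sd_intercept: float

    def __post_init__(self) -> None:
        if self.sd_intercept < 0:
            raise DomainError("sd_intercept must be >= 0")


def fit_calibration(points: Iterable[Sequence[float]]) -> CalibrationCurve:
    """Fit response = slope * concentration + intercept by OLS.

    Requires at least 3 points with at least 2 distinct concentrations.
    ``sd_intercept`` is the OLS standard error of the intercept (0 for an
    exact fit).
    """
    pts = tuple((float(c), float(r)) for c, r in points)
    if len(pts) < 3:
        raise DomainError(f"calibration needs >= 3 points, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise DomainError("all calibration concentrations identical (singular design)")
    res = stats.linregress(x, y)
    sd_int = float(res.intercept_stderr)
    if not np.isfinite(sd_int):  # n == 2 distinct points edge handled by >= 3 check
        sd_int = 0.0
    return CalibrationCurve(
        points=pts,
        slope=float(res.slope),
        intercept=float(res.intercept),
        sd_intercept=sd_int,
    )


def lod_loq(curve: CalibrationCurve) -> tuple[float, float]:
    """(LOD, LOQ) from a fitted calibration curve; requires slope > 0."""
    if curve.slope <= 0:
        raise UnusableCurveError(
            f"calibration slope must be > 0 for detection limits, got {curve.slope}"
        )
    lod = LOD_FACTOR * curve.sd_intercept / curve.slope
    loq = LOQ_FACTOR * curve.sd_intercept / curve.slope
    return lod, loq
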