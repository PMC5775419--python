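"""Sweat-rate calibration: fitting rising rate against reference rate.

The wet-cup artificial skin provides reference sweat rates; the sensor
responds with capacitance rising rates. Calibration is an ordinary
least-squares line through (sweat rate, rising rate) pairs, summarized by
the field's usual curve metrics:

sensitivity
    the fitted slope, (pF/s)/(g/m²h);
linearity
    100·R² of the fit, in percent;
uncertainty
    the residual standard error of the rising rate expressed in sweat-rate
    units (divided by |slope|), g/m²h;
limit of detection
    a fixed multiple of the uncertainty (default multiplier 2.12).

The linearity/uncertainty/LOD conventions are reconstructions — standard
choices consistent with the device's reported figures — and both the
definitions' knobs (``lod_multiplier``) and the reporting rounding are
configurable. Rounding is applied only when formatting for reports, never
inside computations.

Wind robustness compares curves fitted under different air-velocity bins:
the maximum relative sensitivity spread (against the smallest sensitivity)
and the maximum absolute linearity difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, DomainError

DEFAULT_LOD_MULTIPLIER = 2.12


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: wet-cup reference rate vs fitted slope."""

    sweat_rate_gm2h: float
    rising_rate_pf_per_s: float

    def __post_init__(self) -> None:
        if self.sweat_rate_gm2h <= 0:
            raise DomainError("reference sweat rate must be positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted calibration line and its derived metrics."""

    sensitivity: float  # slope, (pF/s)/(g/m²h)
    intercept: float  # pF/s
    linearity_pct: float  # 100·R²
    uncertainty_gm2h: float  # residual SE / |slope|
    lod_gm2h: float  # lod_multiplier × uncertainty
    n_points: int
    lod_multiplier: float = DEFAULT_LOD_MULTIPLIER
    sensitivity_se: float = float("nan")  # standard error of the slope


@dataclass(frozen=True)
class SweatRateEstimate:
    """A sweat rate inverted from a rising rate, with an LOD flag."""

    sweat_rate_gm2h: float
    below_detection: bool


def fit_calibration(
    points: list[CalibrationPoint],
    lod_multiplier: float = DEFAULT_LOD_MULTIPLIER,
) -> CalibrationCurve:
    """OLS fit of rising rate on sweat rate with curve metrics.

    Requires at least 3 points at ≥ 2 distinct sweat rates.
    """
    if len(points) < 3:
        raise CalibrationError(f"need >= 3 points, got {len(points)}")
    x = np.array([p.sweat_rate_gm2h for p in points])
    y = np.array([p.rising_rate_pf_per_s for p in points])
    if np.unique(x).size < 2:
        raise CalibrationError("need >= 2 distinct sweat rates")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rse = math.sqrt(float(np.sum(resid**2)) / (x.size - 2))
    if fit.slope == 0:
        raise CalibrationError("degenerate fit: zero sensitivity")
    uncertainty = rse / abs(fit.slope)
    return CalibrationCurve(
        sensitivity=float(fit.slope),
        intercept=float(fit.intercept),
        linearity_pct=100.0 * float(fit.rvalue) ** 2,
        uncertainty_gm2h=uncertainty,
        lod_gm2h=lod_multiplier * uncertainty,
        n_points=x.size,
        lod_multiplier=lod_multiplier,
        sensitivity_se=float(fit.stderr),
    )


def predict_rising_rate(sweat_rate: float, curve: CalibrationCurve) -> float:
    """Forward prediction: rising rate at a given sweat rate."""
    return curve.intercept + curve.sensitivity * sweat_rate


def apply_calibration(slope_pf_per_s: float, curve: CalibrationCurve) -> SweatRateEstimate:
    """Invert the calibration line: sweat rate = (slope − intercept)/sensitivity.

    Estimates below the curve's limit of detection are flagged.
    """
    if curve.sensitivity == 0:
        raise CalibrationError("curve has zero sensitivity")
    rate = (slope_pf_per_s - curve.intercept) / curve.sensitivity
    return SweatRateEstimate(sweat_rate_gm2h=rate, below_detection=rate < curve.lod_gm2h)


def wind_robustness(
    curves: list[tuple[str, CalibrationCurve]],
) -> tuple[float, float]:
    """Sensitivity and linearity spread across wind-bin calibration curves.

    Returns ``(max relative sensitivity difference %, max absolute
    linearity difference %)``: 100·(max−min)/min over the sensitivities,
    and the largest pairwise linearity gap. Permutation-invariant.
    """
    if len(curves) < 2:
        raise DomainError("need >= 2 curves")
    sens = [c.sensitivity for _, c in curves]
    lin = [c.linearity_pct for _, c in curves]
    s_min, s_max = min(sens), max(sens)
    if s_min <= 0:
        raise DomainError("sensitivities must be positive")
    return 100.0 * (s_max - s_min) / s_min, max(lin) - min(lin)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, for report formatting."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


def temperature_offset(
    temp_coefficient: float,
    t_low_c: float,
    t_high_c: float,
    humidity_sensitivity: float = 0.6,
) -> tuple[float, float]:
    """Capacitance offset of a chamber warm-up and its %RH equivalent.

    The heater warms the chamber by ``t_high_c − t_low_c`` during a cycle;
    with a sensor temperature coefficient in pF/°C this shifts the
    capacitance by a constant offset, equivalent to a humidity change of
    ``offset / humidity_sensitivity``. Both are reported rounded half-up to
    one decimal, the convention used for the device's quoted figures. The
    offset does not affect the rising rate, which is a slope.
    """
    if humidity_sensitivity <= 0:
        raise DomainError("humidity sensitivity must be positive")
    if t_high_c < t_low_c:
        raise DomainError("t_high must be >= t_low")
    offset = round_half_up(temp_coefficient * (t_high_c - t_low_c), 1)
    return offset, round_half_up(offset / humidity_sensitivity, 1)
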