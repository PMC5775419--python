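"""From a capacitance trace to per-cycle capacitance rising rates.

The chamber timing is always known from the heater drive, so cycle
segmentation is deterministic: each period contributes one detection
window (the 13 s following the 2 s contact stabilization), and the
capacitance rising rate is the ordinary least-squares slope over that
window. Saturation — the chamber hitting 100 %RH before the window ends,
as happens at very high sweat rates — is flagged by comparing the slopes
of the two window halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateWindowError,
    FormatError,
    InsufficientDataError,
)
from .synth import CapacitanceTrace, CycleTiming, DEFAULT_TIMING


@dataclass
class DetectionWindow:
    """Samples of one cycle's sweat-rate detection interval.

    Times are window-relative seconds (first detection sample at t = 0);
    the window is half-open at its end.
    """

    cycle_index: int
    times_s: np.ndarray
    capacitances_pf: np.ndarray
    expected_samples: int

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class RisingRateResult:
    """OLS fit of capacitance versus time over a detection window."""

    cycle_index: int
    slope_pf_per_s: float
    intercept_pf: float
    r_squared: float
    n_samples: int
    saturated: bool = False
    degenerate: bool = False  # constant capacitance: slope 0, R² undefined


def segment_cycles(
    trace: CapacitanceTrace,
    timing: CycleTiming = DEFAULT_TIMING,
    min_fraction: float = 0.5,
) -> list[DetectionWindow]:
    """Split a trace into per-cycle detection windows.

    One window per complete cycle; a partial trailing cycle is dropped, and
    windows retaining less than ``min_fraction`` of their expected samples
    are rejected. A trace shorter than one cycle yields an empty list.

    Raises
    ------
    FormatError
        If the trace sampling rate does not match the timing schedule.
    """
    times = trace.times_s
    if times.size == 0:
        return []
    dt = 1.0 / timing.sampling_rate_hz
    if times.size > 1:
        steps = np.diff(times)
        if np.any(np.abs(steps - dt) > 1e-6):
            raise FormatError(
                f"trace is not uniform at {timing.sampling_rate_hz} Hz"
            )
    t0 = times[0]
    duration = times[-1] - t0 + dt
    n_cycles = int(np.floor(duration / timing.period_s + 1e-9))
    expected = int(round(timing.detection_s * timing.sampling_rate_hz))

    windows = []
    t_rel = times - t0
    cycle_of = np.floor(t_rel / timing.period_s + 1e-9).astype(int)
    in_cycle = t_rel - cycle_of * timing.period_s
    for c in range(n_cycles):
        mask = (
            (cycle_of == c)
            & (in_cycle >= timing.detection_start_s - 1e-9)
            & (in_cycle < timing.contact_end_s - 1e-9)
        )
        n = int(mask.sum())
        if n < min_fraction * expected:
            continue
        w_times = times[mask]
        windows.append(
            DetectionWindow(
                cycle_index=c,
                times_s=w_times - w_times[0],
                capacitances_pf=trace.capacitances_pf[mask],
                expected_samples=expected,
            )
        )
    return windows


def rising_rate(window: DetectionWindow) -> RisingRateResult:
    """Capacitance rising rate: OLS slope over the detection window.

    The slope is invariant to capacitance offsets and time-origin shifts.
    A constant-capacitance window has an undefined R²; it is reported as
    slope 0, R² 0 with the ``degenerate`` flag set.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 samples.
    DegenerateWindowError
        Zero time variance (all samples at one instant).
    """
    t = window.times_s
    c = window.capacitances_pf
    if t.size < 3:
        raise InsufficientDataError(f"window has {t.size} samples; need >= 3")
    t = t - t[0]
    t_mean = t.mean()
    c_mean = c.mean()
    s_tt = float(np.sum((t - t_mean) ** 2))
    if s_tt == 0.0:
        raise DegenerateWindowError("zero time variance in window")
    if np.all(c == c[0]):
        return RisingRateResult(
            cycle_index=window.cycle_index,
            slope_pf_per_s=0.0,
            intercept_pf=c_mean,
            r_squared=0.0,
            n_samples=t.size,
            degenerate=True,
        )
    s_tc = float(np.sum((t - t_mean) * (c - c_mean)))
    slope = s_tc / s_tt
    intercept = c_mean - slope * t_mean
    s_cc = float(np.sum((c - c_mean) ** 2))
    r2 = s_tc * s_tc / (s_tt * s_cc)
    return RisingRateResult(
        cycle_index=window.cycle_index,
        slope_pf_per_s=slope,
        intercept_pf=intercept,
        r_squared=r2,
        n_samples=t.size,
    )


def _half_slope(t: np.ndarray, c: np.ndarray) -> float:
    t = t - t.mean()
    s_tt = float(np.sum(t * t))
    return float(np.sum(t * (c - c.mean()))) / s_tt


def detect_saturation(window: DetectionWindow, ratio_threshold: float = 0.1) -> bool:
    """Flag a window whose rise flattens out before the window ends.

    The window is split in half; saturation is declared when the
    second-half OLS slope falls below ``ratio_threshold`` times a positive
    first-half slope. A flat window never saturates (nothing rose).

    Raises
    ------
    InsufficientDataError
        If either half has fewer than 3 samples.
    """
    n = len(window)
    half = n // 2
    if half < 3 or n - half < 3:
        raise InsufficientDataError("each half needs >= 3 samples")
    t, c = window.times_s, window.capacitances_pf
    first = _half_slope(t[:half], c[:half])
    if first <= 0:
        return False
    second = _half_slope(t[half:], c[half:])
    return second < ratio_threshold * first


def extract_rates(
    trace: CapacitanceTrace,
    timing: CycleTiming = DEFAULT_TIMING,
    ratio_threshold: float = 0.1,
) -> list[RisingRateResult]:
    """Segment a trace and fit every detection window, flagging saturation."""
    results = []
    for window in segment_cycles(trace, timing):
        result = rising_rate(window)
        try:
            result.saturated = detect_saturation(window, ratio_threshold)
        except InsufficientDataError:
            result.saturated = False
        results.append(result)
    return results
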