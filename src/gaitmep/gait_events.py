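"""Kinematic gait-event detection and spatiotemporal metrics.

Heel strike is detected as the per-cycle minimum of the heel marker's
vertical trajectory; toe-off as the per-cycle maximum of its upward
acceleration.  Both detectors constrain candidate events to be at least
half a (autocorrelation-estimated) stride apart to avoid double
detection.  Spatiotemporal metrics: step width is the mediolateral
distance between the heels at each heel strike, stride duration is the
interval between consecutive right heel strikes; both are summarised by
mean and sample variance over a trailing stride window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "GaitEvents",
    "SpatiotemporalSummary",
    "detect_heel_strikes",
    "detect_toe_offs",
    "detect_events",
    "compute_step_width",
    "compute_stride_durations",
    "summarize_spatiotemporal",
]


@dataclass
class GaitEvents:
    """Heel-strike and toe-off times (s) per side, each strictly increasing."""

    hs_left: np.ndarray
    hs_right: np.ndarray
    to_left: np.ndarray
    to_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("hs_left", "hs_right", "to_left", "to_right"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, arr)


@dataclass
class SpatiotemporalSummary:
    step_width_mean: float  # mm
    step_width_var: float  # mm^2
    stride_duration_mean: float  # s
    stride_duration_var: float  # s^2
    n_strides: int

    def __post_init__(self) -> None:
        if self.n_strides <= 0:
            raise ValueError("n_strides must be positive")
        if self.step_width_var < 0 or self.stride_duration_var < 0:
            raise ValueError("variances must be non-negative")


def _lowpass(x: np.ndarray, rate: float, cutoff: float = 10.0) -> np.ndarray:
    """Zero-phase low-pass; stabilises minima/acceleration peak locations."""
    sos = signal.butter(2, cutoff, btype="low", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def _estimate_period_samples(x: np.ndarray, rate: float) -> int:
    """Dominant period (samples) via the first autocorrelation peak."""
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise ValueError("constant trajectory: no gait cycles to detect")
    ac = signal.correlate(x, x, mode="full")[len(x) - 1 :]
    ac /= ac[0]
    # first local max after the zero-lag peak has decayed
    min_lag = max(int(0.3 * rate), 2)  # strides are comfortably > 0.3 s
    peaks, _ = signal.find_peaks(ac[min_lag:])
    if len(peaks) == 0:
        raise ValueError("no periodicity found in trajectory")
    return int(peaks[0] + min_lag)


def detect_heel_strikes(heel_vertical: np.ndarray, rate: float) -> np.ndarray:
    """Heel-strike times: per-cycle minima of the vertical heel trajectory.

    Candidate minima closer together than half the estimated stride are
    suppressed (the larger prominence wins), guarding against double
    detection on flat stance phases.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    z = np.asarray(heel_vertical, dtype=float)
    period = _estimate_period_samples(z, rate)
    if len(z) < 2 * period:
        raise ValueError("trajectory shorter than two strides")
    zs = _lowpass(z, rate)
    prominence = 0.1 * (zs.max() - zs.min())  # reject shallow stance wobbles
    idx, _ = signal.find_peaks(-zs, distance=max(period // 2, 1), prominence=prominence)
    if len(idx) == 0:
        raise ValueError("no heel strikes detected")
    return idx / rate


def detect_toe_offs(heel_vertical: np.ndarray, rate: float) -> np.ndarray:
    """Toe-off times: per-cycle maxima of the heel's upward acceleration.

    The vertical trajectory is low-pass filtered (10 Hz, zero phase), then
    differentiated twice by central differences; maxima of the resulting
    acceleration, separated by at least half a stride, are toe-offs.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    z = np.asarray(heel_vertical, dtype=float)
    period = _estimate_period_samples(z, rate)
    if len(z) < 2 * period:
        raise ValueError("trajectory shorter than two strides")
    zs = _lowpass(z, rate)
    acc = np.gradient(np.gradient(zs, 1.0 / rate), 1.0 / rate)
    prominence = 0.1 * (acc.max() - acc.min())  # one dominant burst per cycle
    idx, _ = signal.find_peaks(acc, distance=max(period // 2, 1), prominence=prominence)
    if len(idx) == 0:
        raise ValueError("no toe-offs detected")
    return idx / rate


def detect_events(
    left_heel_vertical: np.ndarray, right_heel_vertical: np.ndarray, rate: float
) -> GaitEvents:
    """Detect all four event streams from the two heel markers."""
    return GaitEvents(
        hs_left=detect_heel_strikes(left_heel_vertical, rate),
        hs_right=detect_heel_strikes(right_heel_vertical, rate),
        to_left=detect_toe_offs(left_heel_vertical, rate),
        to_right=detect_toe_offs(right_heel_vertical, rate),
    )


def compute_step_width(
    left_heel_ml: np.ndarray,
    right_heel_ml: np.ndarray,
    events: GaitEvents,
    rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step widths: |left ML - right ML| at each heel strike.

    Both feet ride the treadmill surface, so a lateral belt displacement
    moves both markers equally at contact and cancels in the difference.
    Returns ``(times, widths_mm)`` over heel strikes of both sides in
    chronological order; heel positions are evaluated at the nearest
    sample.  Raises IndexError for events outside the trajectory span.
    """
    n = len(left_heel_ml)
    times = np.sort(np.concatenate([events.hs_left, events.hs_right]))
    idx = np.round(times * rate).astype(int)
    if np.any(idx < 0) or np.any(idx >= n):
        raise IndexError("heel-strike event outside trajectory span")
    widths = np.abs(
        np.asarray(left_heel_ml, dtype=float)[idx]
        - np.asarray(right_heel_ml, dtype=float)[idx]
    )
    return times, widths


def compute_stride_durations(hs_right: np.ndarray) -> np.ndarray:
    """Stride durations: intervals between consecutive right heel strikes."""
    hs = np.asarray(hs_right, dtype=float)
    if len(hs) < 2:
        raise ValueError("need at least two right heel strikes")
    return np.diff(hs)


def summarize_spatiotemporal(
    widths: np.ndarray, durations: np.ndarray, window: int
) -> SpatiotemporalSummary:
    """Mean and sample variance over the last ``window`` strides.

    ``window`` counts strides; the last ``window`` stride durations and
    the last ``2*window`` step widths (two steps per stride) enter the
    summary.  Sample variance uses the n-1 denominator.
    """
    durations = np.asarray(durations, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if window > len(durations):
        raise ValueError(
            f"window of {window} strides exceeds {len(durations)} available"
        )
    n_steps = 2 * window
    if n_steps > len(widths):
        warnings.warn(
            "fewer step widths than 2x window; using all available", stacklevel=2
        )
        n_steps = len(widths)
    d = durations[-window:]
    w = widths[-n_steps:]
    return SpatiotemporalSummary(
        step_width_mean=float(w.mean()),
        step_width_var=float(w.var(ddof=1)) if len(w) > 1 else 0.0,
        stride_duration_mean=float(d.mean()),
        stride_duration_var=float(d.var(ddof=1)) if len(d) > 1 else 0.0,
        n_strides=window,
    )
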