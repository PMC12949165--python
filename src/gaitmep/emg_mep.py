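"""EMG filtering, MEP extraction, coil-displacement checks and exclusions.

Surface EMG is band-pass filtered (20-500 Hz, zero phase).  For every
TMS pulse three quantities are extracted per muscle: the ongoing EMG
(rectified mean over -20..+10 ms around the pulse, with the artifact
sample at the pulse excluded), the absolute MEP (peak-to-peak amplitude
10-60 ms post pulse), and the MEP gain (absolute MEP divided by ongoing
EMG — corticospinal excitability beyond background drive).  Pulses are
assigned a gait-cycle percentage relative to the bracketing right heel
strikes, checked against coil-displacement thresholds derived from a
helmet/head virtual marker, and participants with too few surviving
pulses in either condition are flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "StimulationRecord",
    "bandpass_filter",
    "compute_ongoing_emg",
    "compute_absolute_mep",
    "compute_mep_gain",
    "compute_virtual_marker_displacement",
    "apply_exclusions",
    "assign_cycle_percentage",
]

VERTICAL_THRESHOLD_MM = 5.0
HORIZONTAL_THRESHOLD_MM = 10.0
MIN_STIMS_PER_CONDITION = 100


@dataclass
class StimulationRecord:
    """Per-pulse measurements for one participant and condition."""

    stim_time: float  # s
    cycle_pct: float  # % of the right-HS-to-right-HS interval, [0, 100)
    coil_vertical: float = 0.0  # mm
    coil_horizontal: float = 0.0  # mm
    included: bool = True
    ongoing_emg: dict[str, float] = field(default_factory=dict)  # uV
    absolute_mep: dict[str, float] = field(default_factory=dict)  # uV
    mep_gain: dict[str, float] = field(default_factory=dict)  # NaN if undefined

    def __post_init__(self) -> None:
        if not (0.0 <= self.cycle_pct < 100.0):
            raise ValueError("cycle_pct must lie in [0, 100)")


def bandpass_filter(
    raw_emg: np.ndarray, rate: float, low: float = 20.0, high: float = 500.0
) -> np.ndarray:
    """Zero-phase 20-500 Hz band-pass (2nd-order design, forward-backward).

    The bidirectional pass doubles the effective order and cancels phase
    distortion, which matters because MEP amplitude is read from narrow
    post-stimulus windows.  DC and movement artifact fall below the 20 Hz
    edge and are removed.
    """
    if rate <= 2 * high:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {high} Hz band edge"
        )
    sos = signal.butter(2, [low, high], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(raw_emg, dtype=float))


def _window_indices(
    stim_index: int, rate: float, start_ms: float, end_ms: float, n: int
) -> np.ndarray:
    """Inclusive sample window [stim+start_ms, stim+end_ms], ms rounded."""
    lo = stim_index + int(round(start_ms * rate / 1000.0))
    hi = stim_index + int(round(end_ms * rate / 1000.0))
    if lo < 0 or hi >= n:
        raise ValueError("analysis window extends beyond the recording")
    return np.arange(lo, hi + 1)


def compute_ongoing_emg(filtered: np.ndarray, stim_index: int, rate: float) -> float:
    """Rectified mean EMG from 20 ms before to 10 ms after the pulse.

    The single sample at the stimulation instant carries the stimulation
    artifact and is removed before averaging, so the result is invariant
    to the artifact sample's value.
    """
    x = np.asarray(filtered, dtype=float)
    idx = _window_indices(stim_index, rate, -20.0, 10.0, len(x))
    idx = idx[idx != stim_index]
    return float(np.mean(np.abs(x[idx])))


def compute_absolute_mep(filtered: np.ndarray, stim_index: int, rate: float) -> float:
    """Peak-to-peak amplitude in the 10-60 ms post-stimulus window."""
    x = np.asarray(filtered, dtype=float)
    idx = _window_indices(stim_index, rate, 10.0, 60.0, len(x))
    seg = x[idx]
    return float(seg.max() - seg.min())


def compute_mep_gain(absolute_mep: float, ongoing_emg: float) -> float:
    """MEP gain = absolute MEP / ongoing EMG; NaN when background is zero.

    A zero-background pulse has no defined gain; it is flagged missing
    (NaN, omitted downstream) rather than mapped to infinity.
    """
    if ongoing_emg < 0 or absolute_mep < 0:
        raise ValueError("amplitudes must be non-negative")
    if ongoing_emg == 0:
        return float("nan")
    return absolute_mep / ongoing_emg


def _rigid_transform(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping src points onto dst."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 paired markers")
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise ValueError("markers are collinear; rigid transform is ambiguous")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, dc - r @ sc


def compute_virtual_marker_displacement(
    calib_helmet: np.ndarray,
    calib_head: np.ndarray,
    calib_virtual: np.ndarray,
    helmet_now: np.ndarray,
    head_now: np.ndarray,
) -> tuple[float, float]:
    """Helmet-vs-head disagreement on the coil's virtual marker position.

    A static calibration records the helmet markers, the head markers and
    a virtual marker at the coil centre.  At a stimulation instant, each
    rigid set's least-squares transform from calibration predicts where
    the virtual marker should be; the head-predicted minus helmet-predicted
    difference measures how far the coil has slipped relative to the head.
    Returns ``(|vertical| mm, horizontal-plane norm mm)``; axes are
    (ML, AP, vertical) with the vertical as the third component.
    """
    r_helmet, t_helmet = _rigid_transform(calib_helmet, helmet_now)
    r_head, t_head = _rigid_transform(calib_head, head_now)
    v = np.asarray(calib_virtual, dtype=float)
    predicted_helmet = r_helmet @ v + t_helmet
    predicted_head = r_head @ v + t_head
    delta = predicted_head - predicted_helmet
    return float(abs(delta[2])), float(np.hypot(delta[0], delta[1]))


def apply_exclusions(
    records: list[StimulationRecord],
    min_per_condition: int = MIN_STIMS_PER_CONDITION,
    vertical_threshold: float = VERTICAL_THRESHOLD_MM,
    horizontal_threshold: float = HORIZONTAL_THRESHOLD_MM,
) -> tuple[list[StimulationRecord], bool]:
    """Drop pulses with excessive coil displacement; flag sparse participants.

    A pulse is excluded iff coil displacement is strictly greater than
    5 mm vertically or strictly greater than 10 mm in the horizontal
    plane; displacements exactly at a threshold survive.  The participant
    is flagged for exclusion when fewer than ``min_per_condition`` pulses
    survive.  Returns ``(surviving records, participant_included)``.
    """
    surviving = []
    for rec in records:
        excluded = (
            rec.coil_vertical > vertical_threshold
            or rec.coil_horizontal > horizontal_threshold
        )
        rec.included = not excluded
        if rec.included:
            surviving.append(rec)
    return surviving, len(surviving) >= min_per_condition


def assign_cycle_percentage(stim_time: float, hs_right: np.ndarray) -> float | None:
    """Gait-cycle percentage of a pulse between bracketing right heel strikes.

    Returns ``100 * (t - previous HS) / (next HS - previous HS)``, or None
    (with a warning) for pulses outside the event span.
    """
    hs = np.asarray(hs_right, dtype=float)
    if len(hs) < 2:
        raise ValueError("need at least two right heel strikes")
    if stim_time < hs[0] or stim_time >= hs[-1]:
        warnings.warn(
            f"stimulation at {stim_time:.3f} s outside heel-strike span; excluded",
            stacklevel=2,
        )
        return None
    k = int(np.searchsorted(hs, stim_time, side="right") - 1)
    return float(100.0 * (stim_time - hs[k]) / (hs[k + 1] - hs[k]))
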