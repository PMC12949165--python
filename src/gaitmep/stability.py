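"""Local dynamic stability of gait via the local divergence exponent.

The local divergence exponent (lambda_s) quantifies how quickly nearby
trajectories in a reconstructed state space diverge, i.e. how sensitive
the walking pattern is to small perturbations.  The state space is built
from the stride-time-normalised mediolateral velocity of the thorax and
five time-delayed copies (6-D delay embedding).  Rosenstein's algorithm
tracks, for every point, the distance to its nearest neighbour (excluding
temporally adjacent points) as both evolve forward in time; lambda_s is
the slope of the mean log-divergence curve over the first half stride.
Larger lambda_s means locally less stable gait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.spatial import cKDTree

__all__ = [
    "StateSpace",
    "DivergenceCurve",
    "time_normalize_strides",
    "delay_embed",
    "build_state_space",
    "rosenstein_divergence",
    "estimate_lambda_s",
    "lambda_s_from_velocity",
]

N_DELAY_COPIES = 5  # embedding uses the series plus five delayed copies


@dataclass
class StateSpace:
    """Delay-embedded state matrix on the stride-normalised time axis."""

    matrix: np.ndarray  # (n_points, 6)
    samples_per_stride: int
    delay: int
    n_strides: int

    def __post_init__(self) -> None:
        expected = self.n_strides * self.samples_per_stride - N_DELAY_COPIES * self.delay
        if self.matrix.shape != (expected, N_DELAY_COPIES + 1):
            raise ValueError(
                f"state matrix shape {self.matrix.shape} inconsistent with "
                f"{self.n_strides} strides x {self.samples_per_stride} samples, "
                f"delay {self.delay}"
            )


@dataclass
class DivergenceCurve:
    """Mean log divergence vs. forward time in strides."""

    time_strides: np.ndarray
    mean_log_divergence: np.ndarray


def time_normalize_strides(
    series: np.ndarray,
    stride_times: np.ndarray,
    rate: float,
    n_strides: int,
    samples_per_stride: int = 100,
) -> np.ndarray:
    """Resample a series so each stride spans a fixed number of samples.

    ``stride_times`` are the (right) heel-strike times delimiting strides.
    Each stride is linearly interpolated onto ``samples_per_stride``
    equally spaced phases [0, 1); the per-stride endpoint (phase 0) equals
    the original series at the stride-start sample when that event lies on
    the sample grid.
    """
    series = np.asarray(series, dtype=float)
    stride_times = np.asarray(stride_times, dtype=float)
    if len(stride_times) < n_strides + 1:
        raise ValueError(
            f"need {n_strides + 1} heel strikes for {n_strides} strides, "
            f"got {len(stride_times)}"
        )
    t = np.arange(len(series)) / rate
    f = interp1d(t, series, kind="linear", assume_sorted=True)
    out = np.empty(n_strides * samples_per_stride)
    for k in range(n_strides):
        t0, t1 = stride_times[k], stride_times[k + 1]
        phases = t0 + (t1 - t0) * np.arange(samples_per_stride) / samples_per_stride
        out[k * samples_per_stride : (k + 1) * samples_per_stride] = f(phases)
    return out


def delay_embed(series: np.ndarray, delay: int, n_copies: int = N_DELAY_COPIES) -> np.ndarray:
    """Delay-embed a scalar series into ``n_copies + 1`` dimensions."""
    series = np.asarray(series, dtype=float)
    n = len(series) - n_copies * delay
    if n <= 0:
        raise ValueError("series too short for requested embedding")
    cols = [series[j * delay : j * delay + n] for j in range(n_copies + 1)]
    return np.column_stack(cols)


def build_state_space(
    velocity: np.ndarray,
    stride_times: np.ndarray,
    rate: float,
    n_strides: int,
    samples_per_stride: int = 100,
    delay: int = 10,
) -> StateSpace:
    """Stride-normalise the thorax ML velocity and delay-embed it.

    delay=10 samples (10% of a 100-sample stride) follows the convention
    of the gait local-dynamic-stability literature.
    """
    normalized = time_normalize_strides(
        velocity, stride_times, rate, n_strides, samples_per_stride
    )
    matrix = delay_embed(normalized, delay) if delay > 0 else np.column_stack(
        [normalized] * (N_DELAY_COPIES + 1)
    )
    return StateSpace(
        matrix=matrix,
        samples_per_stride=samples_per_stride,
        delay=delay,
        n_strides=n_strides,
    )


def rosenstein_divergence(
    space: StateSpace | np.ndarray,
    horizon_strides: float = 10.0,
    samples_per_stride: int | None = None,
    theiler: int | None = None,
) -> DivergenceCurve:
    """Mean log-divergence curve of nearest state-space neighbours.

    For every point the nearest Euclidean neighbour outside a temporal
    exclusion (Theiler) window of half a stride is found; the pair is
    followed forward and the log of their distance averaged over all
    pairs at each forward step.  A plain ``(n, d)`` array may be passed
    with explicit ``samples_per_stride`` (e.g. 1 to work in units of
    iterates for map data).
    """
    if isinstance(space, StateSpace):
        matrix = space.matrix
        sps = space.samples_per_stride
    else:
        matrix = np.asarray(space, dtype=float)
        if samples_per_stride is None:
            raise ValueError("samples_per_stride required for raw matrices")
        sps = samples_per_stride
    n = len(matrix)
    if theiler is None:
        theiler = max(sps // 2, 1)
    if theiler < 1:
        raise ValueError("temporal exclusion window must be >= 1 sample")
    horizon = int(round(horizon_strides * sps))
    if n <= 2 * theiler + 1:
        raise ValueError("too few points for the temporal exclusion window")

    tree = cKDTree(matrix)
    # query enough neighbours that at least one falls outside the Theiler
    # window; all points within the window could in principle be nearer
    k = min(2 * theiler + 2, n)
    dists, nbrs = tree.query(matrix, k=k, workers=-1)
    neighbour = np.full(n, -1, dtype=int)
    for i in range(n):
        mask = np.abs(nbrs[i] - i) > theiler
        if mask.any():
            # ties at equal distance: query returns index order; take first
            neighbour[i] = nbrs[i][mask][0]
    valid = neighbour >= 0
    if not valid.any():
        raise ValueError("all candidate neighbours excluded by Theiler window")

    idx_i = np.nonzero(valid)[0]
    idx_j = neighbour[valid]
    curve = np.full(horizon + 1, np.nan)
    with np.errstate(divide="ignore"):
        for h in range(horizon + 1):
            keep = (idx_i + h < n) & (idx_j + h < n)
            if not keep.any():
                break
            d = np.linalg.norm(matrix[idx_i[keep] + h] - matrix[idx_j[keep] + h], axis=1)
            logs = np.log(d[d > 0])
            if len(logs):
                curve[h] = logs.mean()
    defined = np.isfinite(curve)
    return DivergenceCurve(
        time_strides=np.arange(horizon + 1)[defined] / sps,
        mean_log_divergence=curve[defined],
    )


def estimate_lambda_s(
    curve: DivergenceCurve, fit_window_strides: tuple[float, float] = (0.0, 0.5)
) -> float:
    """Slope of the mean divergence curve over 0-0.5 strides (inclusive)."""
    lo, hi = fit_window_strides
    mask = (curve.time_strides >= lo) & (curve.time_strides <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValueError("divergence curve does not cover the fit window")
    slope, _ = np.polyfit(
        curve.time_strides[mask], curve.mean_log_divergence[mask], 1
    )
    return float(slope)


def lambda_s_from_velocity(
    velocity: np.ndarray,
    stride_times: np.ndarray,
    rate: float,
    n_strides: int,
    samples_per_stride: int = 100,
    delay: int = 10,
    horizon_strides: float = 10.0,
) -> tuple[float, DivergenceCurve]:
    """Convenience wrapper: embed, diverge and fit in one call."""
    space = build_state_space(
        velocity, stride_times, rate, n_strides, samples_per_stride, delay
    )
    curve = rosenstein_divergence(space, horizon_strides=horizon_strides)
    return estimate_lambda_s(curve), curve
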