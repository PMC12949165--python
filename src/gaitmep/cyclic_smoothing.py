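"""Cyclic kernel smoothing of sparse gait-phase samples.

Outcomes sampled sparsely over the gait cycle (one value per stimulation,
at the stimulation's cycle percentage) are reconstructed as continuous
cyclic curves by Nadaraya-Watson regression with a Von Mises kernel.  The
Von Mises distribution is the circular analogue of the Gaussian: using it
instead of a Gaussian makes the smoother respect the wrap-around at
0%/100% of the cycle.  Kernel-density weights are carried along so that
group averages can optionally weight each participant by their local
sample density, and a minimum-density rule flags grid points where too few
samples support the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e

__all__ = [
    "CyclicGrid",
    "SmoothedCyclicSeries",
    "kappa_from_sigma",
    "vonmises_weights",
    "smooth_participant",
    "check_density_rule",
    "group_average",
]


@dataclass(frozen=True)
class CyclicGrid:
    """Regular grid over the gait cycle, in percent, covering [0, 100).

    Parameters
    ----------
    resolution : float
        Grid spacing in percent of the gait cycle.  Must divide 100.
    """

    resolution: float = 0.5

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        n = 100.0 / self.resolution
        if abs(n - round(n)) > 1e-9:
            raise ValueError("resolution must divide 100")

    @property
    def n_points(self) -> int:
        return int(round(100.0 / self.resolution))

    @property
    def pcts(self) -> np.ndarray:
        """Grid points in percent of the gait cycle."""
        return np.arange(self.n_points) * self.resolution

    @property
    def angles(self) -> np.ndarray:
        """Grid points as angles on the unit circle (radians)."""
        return self.pcts * (2.0 * np.pi / 100.0)


@dataclass
class SmoothedCyclicSeries:
    """A smoothed cyclic curve with its kernel-density weights.

    ``values[t]`` is the density-normalised kernel regression estimate at
    grid point ``t``; ``density[t]`` is the un-normalised sum of kernel
    weights there (a "samples-equivalent" local density); ``valid[t]``
    flags grid points that satisfy the minimum-sample density rule.
    """

    grid: CyclicGrid
    values: np.ndarray
    density: np.ndarray
    valid: np.ndarray | None = None
    kappa: float = field(default=np.nan)
    sigma_pct: float = field(default=np.nan)

    def __post_init__(self) -> None:
        n = self.grid.n_points
        if len(self.values) != n or len(self.density) != n:
            raise ValueError("values/density length must match grid")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


def kappa_from_sigma(sigma_pct: float, rounded: bool = False) -> float:
    """Von Mises concentration equivalent to a Gaussian of width ``sigma_pct``.

    For large concentration the Von Mises distribution approaches a wrapped
    Gaussian with variance 1/kappa, so a Gaussian kernel of standard
    deviation ``sigma_pct`` (percent of cycle) maps to
    ``kappa = 1 / sigma_rad**2`` with ``sigma_rad = 2*pi*sigma_pct/100``.

    With ``rounded=True`` the result is rounded to the nearest multiple of
    10, the convention used when quoting the concentration as a round
    number (sigma = 2% of the cycle then gives kappa = 60).
    """
    if sigma_pct <= 0:
        raise ValueError("sigma_pct must be positive")
    sigma_rad = 2.0 * np.pi * sigma_pct / 100.0
    kappa = 1.0 / sigma_rad**2
    if rounded:
        return float(10 * round(kappa / 10.0))
    return float(kappa)


def vonmises_weights(
    sample_pcts: np.ndarray, grid: CyclicGrid, kappa: float
) -> np.ndarray:
    """Von Mises kernel weight matrix between grid points and samples.

    Returns an ``(n_grid, n_samples)`` matrix with
    ``w[t, i] = exp(kappa * cos(theta_t - theta_i)) / (2*pi*I0(kappa))``,
    the Von Mises density of sample ``i`` evaluated at grid point ``t``.
    Computed via the exponentially scaled Bessel function so that large
    concentrations do not overflow.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    sample_pcts = np.asarray(sample_pcts, dtype=float)
    theta_s = sample_pcts * (2.0 * np.pi / 100.0)
    delta = grid.angles[:, None] - theta_s[None, :]
    # exp(k cos d) / (2 pi I0(k)) = exp(k (cos d - 1)) / (2 pi i0e(k))
    return np.exp(kappa * (np.cos(delta) - 1.0)) / (2.0 * np.pi * i0e(kappa))


def smooth_participant(
    sample_pcts: np.ndarray,
    sample_values: np.ndarray,
    grid: CyclicGrid,
    kappa: float,
    sigma_pct: float | None = None,
    min_count: int = 6,
) -> SmoothedCyclicSeries:
    """Smooth one participant-condition's sparse samples onto the cyclic grid.

    The estimate at each grid point is the kernel-weighted mean of the
    sample values (Nadaraya-Watson): the kernel is convolved with the
    outcomes and divided by the summed kernel density so that constant
    inputs map to constant outputs.  Samples with NaN values (e.g. gains
    undefined at zero background activity) are dropped.  If ``sigma_pct``
    is given the minimum-density validity rule is evaluated as well.
    """
    sample_pcts = np.asarray(sample_pcts, dtype=float)
    sample_values = np.asarray(sample_values, dtype=float)
    if sample_pcts.shape != sample_values.shape:
        raise ValueError("sample_pcts and sample_values must have equal shape")
    keep = np.isfinite(sample_values)
    sample_pcts, sample_values = sample_pcts[keep], sample_values[keep]
    if sample_pcts.size == 0:
        raise ValueError("no finite samples to smooth")
    w = vonmises_weights(sample_pcts, grid, kappa)
    density = w.sum(axis=1)
    values = (w @ sample_values) / density
    valid = None
    if sigma_pct is not None:
        valid = check_density_rule(sample_pcts, grid, sigma_pct, min_count)
    return SmoothedCyclicSeries(
        grid=grid,
        values=values,
        density=density,
        valid=valid,
        kappa=kappa,
        sigma_pct=sigma_pct if sigma_pct is not None else np.nan,
    )


def circular_distance_pct(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest distance around the 0-100% cycle, in percent."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 100.0
    return np.minimum(d, 100.0 - d)


def check_density_rule(
    sample_pcts: np.ndarray,
    grid: CyclicGrid,
    sigma_pct: float,
    min_count: int = 6,
) -> np.ndarray:
    """Flag grid points supported by at least ``min_count`` nearby samples.

    A grid point is valid when at least ``min_count`` samples lie within
    two standard deviations (circular distance <= 2*sigma) of it, which
    protects the kernel estimate against being dominated by outliers in
    sparsely sampled phases of the cycle.
    """
    if sigma_pct <= 0:
        raise ValueError("sigma_pct must be positive")
    sample_pcts = np.asarray(sample_pcts, dtype=float)
    d = circular_distance_pct(grid.pcts[:, None], sample_pcts[None, :])
    counts = (d <= 2.0 * sigma_pct).sum(axis=1)
    return counts >= min_count


def group_average(
    series: list[SmoothedCyclicSeries], mode: str = "weighted"
) -> tuple[np.ndarray, np.ndarray]:
    """Average smoothed curves across participants.

    mode="unweighted": plain mean over participants at each grid point.
    mode="weighted": each participant's contribution at a grid point is
    proportional to their kernel density there, so participants with more
    stimulations near that phase dominate the estimate at that phase.

    Returns ``(group_values, weights)`` where ``weights`` is the
    ``(n_participants, n_grid)`` matrix of normalised weights (each column
    sums to 1; uniform in unweighted mode).
    """
    if len(series) < 2:
        raise ValueError("group averaging requires at least two participants")
    grid = series[0].grid
    if any(s.grid.n_points != grid.n_points for s in series):
        raise ValueError("all series must share the same grid")
    values = np.stack([s.values for s in series])
    if mode == "unweighted":
        weights = np.full(values.shape, 1.0 / len(series))
    elif mode == "weighted":
        dens = np.stack([s.density for s in series])
        weights = dens / dens.sum(axis=0, keepdims=True)
    else:
        raise ValueError("mode must be 'weighted' or 'unweighted'")
    return (weights * values).sum(axis=0), weights
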