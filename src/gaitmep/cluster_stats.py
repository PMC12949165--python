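"""Paired cluster-based permutation tests on cyclic curves.

Condition differences in smoothed cyclic curves (one curve per participant
per condition) are tested pointwise with paired t statistics, then
corrected for the multiple dependent comparisons along the cycle by
cluster-based permutation: runs of consecutively significant grid points
with a common sign form clusters, each scored by its summed t value, and
the observed cluster masses are calibrated against the distribution of the
maximal cluster mass under within-participant condition-label exchange.
Because the gait cycle is periodic, runs touching both ends of the grid
are wrapped into a single cluster.

Two pointwise variants are provided: the classical paired t, and a
density-weighted t in which each participant's contribution at a grid
point is proportional to their local stimulation density.  With equal
weights the two coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Cluster",
    "PermutationResult",
    "pointwise_paired_t",
    "find_clusters_cyclic",
    "permutation_null",
    "paired_t_scalar",
    "min_attainable_p",
]

#: Cap applied to t statistics when the paired differences have zero
#: variance (e.g. a constant shift with no noise); the statistic is
#: formally infinite, which would poison cluster masses.
T_CAP = 1e6


@dataclass
class Cluster:
    """A contiguous (possibly wrapped) run of significant grid points."""

    indices: np.ndarray  # grid indices in cycle order (may wrap past the end)
    sign: int
    mass: float
    p_value: float = np.nan

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class PermutationResult:
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    alpha: float
    n_permutations: int
    seed: int
    t_observed: np.ndarray = field(default=None)

    @property
    def min_attainable_p(self) -> float:
        return min_attainable_p(self.n_permutations)

    @property
    def significant_clusters(self) -> list[Cluster]:
        thresh = np.percentile(self.null_max_mass, 100.0 * (1.0 - self.alpha))
        return [c for c in self.clusters if abs(c.mass) > thresh]


def min_attainable_p(n_permutations: int) -> float:
    """Smallest cluster p-value a permutation test of this size can report."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    return 1.0 / n_permutations


def pointwise_paired_t(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    mode: str = "unweighted",
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Paired t statistic at every grid point.

    Parameters
    ----------
    curves_a, curves_b : (n_participants, n_grid) arrays
        One cyclic curve per participant per condition, paired by row.
    mode : "unweighted" | "weighted"
        Unweighted: classical paired t per grid point with n-1 degrees of
        freedom.  Weighted: the condition difference of each participant is
        weighted by the normalised per-point weights ``weights`` (from the
        combined-condition kernel densities); the variance uses
        reliability-weighted deviations, ``s2 = sum(w*(d-dbar)^2)/(1-sum(w^2))``
        with standard error ``sqrt(s2*sum(w^2))``, which reduces exactly to
        the classical paired t when all weights are equal.

    Returns
    -------
    t : (n_grid,) array, df : int
    """
    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves_a and curves_b must have equal shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired t requires at least 2 participants")
    d = a - b
    df = n - 1
    if mode == "unweighted":
        dbar = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        se = sd / np.sqrt(n)
    elif mode == "weighted":
        if weights is None:
            raise ValueError("weighted mode requires a weights matrix")
        w = np.asarray(weights, dtype=float)
        if w.shape != d.shape:
            raise ValueError("weights must match curve shape")
        w = w / w.sum(axis=0, keepdims=True)
        dbar = (w * d).sum(axis=0)
        sum_w2 = (w**2).sum(axis=0)
        s2 = (w * (d - dbar) ** 2).sum(axis=0) / (1.0 - sum_w2)
        se = np.sqrt(s2 * sum_w2)
    else:
        raise ValueError("mode must be 'weighted' or 'unweighted'")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dbar / se
    # zero-variance differences: cap the formally infinite statistic
    degenerate = se == 0
    t[degenerate & (dbar != 0)] = np.sign(dbar[degenerate & (dbar != 0)]) * T_CAP
    t[degenerate & (dbar == 0)] = 0.0
    return t, df


def find_clusters_cyclic(
    t: np.ndarray, t_critical: float, p_values: bool = False
) -> list[Cluster]:
    """Enumerate maximal runs of same-signed supra-threshold grid points.

    Points with ``|t| > t_critical`` (strict) are significant.  Maximal
    runs of consecutive significant points sharing a sign form clusters;
    because the grid is cyclic, a run ending at the last index and a run
    starting at index 0 with the same sign are merged into one wrapped
    cluster.  Each cluster's mass is the sum of its member t values.
    """
    t = np.asarray(t, dtype=float)
    n = len(t)
    sig = np.abs(t) > t_critical
    if not sig.any():
        return []
    signs = np.sign(t).astype(int)
    if sig.all() and np.all(signs == signs[0]):
        # whole cycle is one cluster
        idx = np.arange(n)
        return [Cluster(indices=idx, sign=int(signs[0]), mass=float(t.sum()))]
    # label runs on the linear array
    clusters: list[Cluster] = []
    i = 0
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1] and signs[j + 1] == signs[i]:
                j += 1
            idx = np.arange(i, j + 1)
            clusters.append(
                Cluster(indices=idx, sign=int(signs[i]), mass=float(t[idx].sum()))
            )
            i = j + 1
        else:
            i += 1
    # wrap: merge a cluster touching the end into one touching the start
    if len(clusters) >= 2:
        first, last = clusters[0], clusters[-1]
        if (
            first.indices[0] == 0
            and last.indices[-1] == n - 1
            and first.sign == last.sign
        ):
            merged = Cluster(
                indices=np.concatenate([last.indices, first.indices]),
                sign=first.sign,
                mass=first.mass + last.mass,
            )
            clusters = [merged] + clusters[1:-1]
    return clusters


def _max_cluster_mass(t: np.ndarray, t_critical: float) -> float:
    clusters = find_clusters_cyclic(t, t_critical)
    if not clusters:
        return 0.0
    return max(abs(c.mass) for c in clusters)


def permutation_null(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    mode: str = "unweighted",
    weights: np.ndarray | None = None,
) -> PermutationResult:
    """Cluster-based permutation test on paired cyclic curves.

    Each permutation exchanges the two condition labels within each
    participant with probability 1/2 (equivalently, flips the sign of that
    participant's difference curve), then recomputes the pointwise t
    statistics and the maximal absolute cluster mass.  Observed clusters
    receive ``p = (# null >= |mass|) / n_permutations`` floored at
    ``1/n_permutations``; a cluster is significant when its mass exceeds
    the 95th percentile (at alpha=0.05) of the null distribution.

    For stimulation-level data smoothed per participant-condition, the
    label exchange commutes with smoothing (swapping a participant's
    condition blocks and re-smoothing yields the same two curves,
    swapped), so this curve-level sign flip is exact for the raw-data
    permutation scheme as well.
    """
    import warnings

    if n_permutations < 100:
        warnings.warn(
            "fewer than 100 permutations gives a coarse null distribution",
            stacklevel=2,
        )
    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    n = a.shape[0]
    df = n - 1
    t_critical = stats.t.ppf(1.0 - alpha / 2.0, df)
    t_obs, _ = pointwise_paired_t(a, b, mode=mode, weights=weights)
    clusters = find_clusters_cyclic(t_obs, t_critical)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        flips = rng.integers(0, 2, size=n).astype(bool)
        pa = np.where(flips[:, None], b, a)
        pb = np.where(flips[:, None], a, b)
        t_perm, _ = pointwise_paired_t(pa, pb, mode=mode, weights=weights)
        null[k] = _max_cluster_mass(t_perm, t_critical)

    floor = 1.0 / n_permutations
    for c in clusters:
        p = np.count_nonzero(null >= abs(c.mass)) / n_permutations
        c.p_value = max(p, floor)
    return PermutationResult(
        clusters=clusters,
        null_max_mass=null,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
        t_observed=t_obs,
    )


def paired_t_scalar(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, int, float]:
    """Two-sided paired t test for scalar per-participant outcomes.

    Returns ``(t, df, p)``.  Zero-variance differences (all participants
    shifted identically) yield a capped t with p = 0.0 when the shift is
    non-zero, flagging the degenerate case rather than raising.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    if len(a) < 2:
        raise ValueError("paired t requires at least 2 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, len(a) - 1, 1.0
        return float(np.sign(d.mean()) * T_CAP), len(a) - 1, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)
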