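"""Linear foot-placement-control model over the step cycle.

Mediolateral foot placement during walking is largely predicted by the
state of the centre of mass (CoM) during the preceding single-stance
phase: a linear regression

    foot_placement = beta_pos * PEL_pos(t) + beta_vel * PEL_vel(t) + eps

is fitted at every phase point t of single-leg stance (contralateral
toe-off to heel strike), with the pelvis (mean of the posterior superior
iliac spine markers) as CoM proxy.  All variables are demeaned across
steps so no intercept is needed.  R-squared(t) quantifies how tightly
foot placement is controlled by CoM state at phase t; the standard
deviation of the residual at the placement instant is the foot-placement
error (placement precision in mm).  R-squared values are variance
stabilised with a Fisher transform, atanh(sqrt(R^2)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gait_events import GaitEvents

__all__ = [
    "StepCycleMatrix",
    "FootPlacementFit",
    "extract_step_cycles",
    "fit_model",
    "fisher_transform",
]

N_PHASE_POINTS = 51  # 0..100% of single-leg stance in 2% increments


@dataclass
class StepCycleMatrix:
    """Demeaned predictors and outcome for the foot-placement regression.

    ``position`` and ``velocity`` are (n_steps, n_phase) pelvis states
    relative to the previous stance foot, demeaned per phase point;
    ``outcome`` is the demeaned ML foot placement (mm) of each step.
    """

    position: np.ndarray  # mm
    velocity: np.ndarray  # mm/s
    outcome: np.ndarray  # mm
    phase: np.ndarray  # fraction of single stance, 0..1
    side: str = "right"

    def __post_init__(self) -> None:
        if self.position.shape != self.velocity.shape:
            raise ValueError("position and velocity must have equal shape")
        if len(self.outcome) != self.position.shape[0]:
            raise ValueError("one outcome per step required")

    @property
    def n_steps(self) -> int:
        return self.position.shape[0]


@dataclass
class FootPlacementFit:
    beta_position: np.ndarray  # (n_phase,) mm per mm
    beta_velocity: np.ndarray  # (n_phase,) mm per mm/s
    beta_position_se: np.ndarray
    beta_velocity_se: np.ndarray
    r_squared: np.ndarray  # (n_phase,)
    fisher: np.ndarray
    residuals: np.ndarray  # (n_steps, n_phase)
    fp_error: float  # mm, SD of residual at the placement instant
    n_steps: int


def _event_before(events: np.ndarray, t: float) -> float | None:
    idx = np.searchsorted(events, t) - 1
    if idx < 0:
        return None
    return float(events[idx])


def extract_step_cycles(
    pelvis_ml: np.ndarray,
    left_heel_ml: np.ndarray,
    right_heel_ml: np.ndarray,
    events: GaitEvents,
    rate: float,
    treadmill_displacement: np.ndarray | None = None,
    side: str = "right",
    n_phase: int = N_PHASE_POINTS,
) -> StepCycleMatrix:
    """Build the regression matrix for steps ending on ``side`` heel strikes.

    For each heel strike of the swing side, the single-stance window runs
    from that side's preceding toe-off to the heel strike.  The coordinate
    origin is the contralateral (stance) heel's ML position at its own
    contact instant, which removes slow drift over the treadmill.  The
    velocity predictor is the within-step time derivative of the relative
    pelvis position; when a treadmill lateral-displacement signal is
    supplied its velocity is added, recovering the belt-relative CoM
    velocity on the oscillating surface.  Steps missing a contralateral
    toe-off are skipped with a warning.
    """
    pelvis_ml = np.asarray(pelvis_ml, dtype=float)
    lheel = np.asarray(left_heel_ml, dtype=float)
    rheel = np.asarray(right_heel_ml, dtype=float)
    n = len(pelvis_ml)
    dt = 1.0 / rate
    belt_vel = None
    if treadmill_displacement is not None:
        belt_vel = np.gradient(np.asarray(treadmill_displacement, dtype=float), dt)

    if side == "right":
        hs_swing, to_swing, hs_stance = events.hs_right, events.to_right, events.hs_left
        heel_swing, heel_stance = rheel, lheel
    elif side == "left":
        hs_swing, to_swing, hs_stance = events.hs_left, events.to_left, events.hs_right
        heel_swing, heel_stance = lheel, rheel
    else:
        raise ValueError("side must be 'left' or 'right'")

    phase = np.linspace(0.0, 1.0, n_phase)
    pos_rows, vel_rows, outcomes = [], [], []
    for t_hs in hs_swing:
        t_to = _event_before(to_swing, t_hs)
        t_contact = _event_before(hs_stance, t_hs)
        if t_to is None or t_contact is None or t_to <= t_contact:
            warnings.warn(
                f"step at {t_hs:.3f} s missing a contralateral toe-off; skipped",
                stacklevel=2,
            )
            continue
        i0 = int(round(t_to * rate))
        i1 = int(round(t_hs * rate))
        ic = int(round(t_contact * rate))
        if i0 < 1 or i1 >= n - 1 or i1 - i0 < 3:
            continue
        origin = heel_stance[ic]
        seg = pelvis_ml[i0 : i1 + 1] - origin
        seg_t = (np.arange(i0, i1 + 1) - i0) * dt
        # second-order edges: the placement instant is the window's last
        # sample, and a first-order edge difference biases the velocity
        # there in proportion to the local acceleration
        vel = np.gradient(seg, dt, edge_order=2)
        if belt_vel is not None:
            vel = vel + belt_vel[i0 : i1 + 1]
        tau = phase * seg_t[-1]
        pos_rows.append(np.interp(tau, seg_t, seg))
        vel_rows.append(np.interp(tau, seg_t, vel))
        outcomes.append(heel_swing[i1] - origin)

    if len(pos_rows) < 2:
        raise ValueError("fewer than two usable steps")
    pos = np.asarray(pos_rows)
    vel = np.asarray(vel_rows)
    out = np.asarray(outcomes)
    # orient so the swing foot lands on the positive side of the stance foot
    orient = 1.0 if out.mean() >= 0 else -1.0
    pos, vel, out = orient * pos, orient * vel, orient * out
    return StepCycleMatrix(
        position=pos - pos.mean(axis=0),
        velocity=vel - vel.mean(axis=0),
        outcome=out - out.mean(),
        phase=phase,
        side=side,
    )


def fit_model(matrix: StepCycleMatrix) -> FootPlacementFit:
    """Ordinary least squares of foot placement on CoM state per phase point.

    Predictors and outcome are already demeaned, so the two-coefficient
    model has no intercept.  R-squared is the explained-variance fraction;
    phase points with (near-)collinear or zero-variance predictors are
    flagged with NaN coefficients and R-squared.  ``fp_error`` is the
    sample SD of the residual at the final phase point — the precision of
    the realised foot placement around its model prediction.
    """
    n_steps, n_phase = matrix.position.shape
    if n_steps < 10:
        raise ValueError("need at least 10 steps to fit the model")
    y = matrix.outcome
    ss_tot = float(y @ y)
    beta = np.full((n_phase, 2), np.nan)
    beta_se = np.full((n_phase, 2), np.nan)
    r2 = np.full(n_phase, np.nan)
    resid = np.full((n_steps, n_phase), np.nan)
    for j in range(n_phase):
        x = np.column_stack([matrix.position[:, j], matrix.velocity[:, j]])
        xtx = x.T @ x
        if np.linalg.cond(xtx) > 1e12 or ss_tot == 0:
            continue  # flagged phase point: undefined fit
        b = np.linalg.solve(xtx, x.T @ y)
        e = y - x @ b
        beta[j] = b
        resid[:, j] = e
        ss_res = float(e @ e)
        r2[j] = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
        if n_steps > 2:
            s2 = ss_res / (n_steps - 2)
            beta_se[j] = np.sqrt(s2 * np.diag(np.linalg.inv(xtx)))
    final_resid = resid[:, -1]
    fp_error = (
        float(np.std(final_resid[np.isfinite(final_resid)], ddof=1))
        if np.isfinite(final_resid).sum() > 1
        else float("nan")
    )
    return FootPlacementFit(
        beta_position=beta[:, 0],
        beta_velocity=beta[:, 1],
        beta_position_se=beta_se[:, 0],
        beta_velocity_se=beta_se[:, 1],
        r_squared=r2,
        fisher=fisher_transform(r2),
        residuals=resid,
        fp_error=fp_error,
        n_steps=n_steps,
    )


def fisher_transform(r_squared: np.ndarray) -> np.ndarray:
    """Variance-stabilising transform atanh(sqrt(R^2)).

    atanh requires an argument inside (-1, 1), so the transform acts on
    the correlation-scale sqrt(R^2); values are clipped just below 1 to
    keep perfect fits finite.  NaN inputs (flagged phase points) pass
    through.
    """
    r2 = np.asarray(r_squared, dtype=float)
    finite = np.isfinite(r2)
    if np.any((r2[finite] < 0) | (r2[finite] > 1)):
        raise ValueError("R^2 values must lie in [0, 1]")
    out = np.full_like(r2, np.nan)
    out[finite] = np.arctanh(np.sqrt(np.clip(r2[finite], 0.0, 1.0 - 1e-12)))
    return out
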