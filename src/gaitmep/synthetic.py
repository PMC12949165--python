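"""Synthetic treadmill-gait sessions with known ground truth.

Generates complete sessions — marker kinematics, EMG with injected motor
evoked potentials (MEPs), stimulation schedules and coil displacements —
whose statistical structure matches what the analysis modules assume, so
every estimator in the package can be validated against stored truth:

* a pseudorandom mediolateral treadmill oscillation (multi-sine with
  incommensurate frequencies, exact peak-to-peak rescaling);
* heel trajectories built from a smooth periodic template whose per-cycle
  vertical minimum and upward-acceleration maximum define the true heel
  strikes and toe-offs;
* mediolateral foot placement that follows the linear CoM-state control
  law ``placement = beta_pos * pos + beta_vel * vel + eps`` with
  configurable coefficients and residual noise, constructed so the
  regression in :mod:`gaitmep.foot_placement` recovers the coefficients;
* phasically modulated EMG with damped-sinusoid MEPs whose peak-to-peak
  amplitude follows ``gain(cycle %) x pre-stimulus activity``;
* per-stimulation coil displacement with a controlled threshold
  exceedance rate, and a motor-threshold staircase simulator.

All randomness derives from one root seed through named child streams, so
identical configurations give bit-identical sessions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "MUSCLES",
    "ConditionParams",
    "SessionConfig",
    "SyntheticGroundTruth",
    "MarkerTimeSeries",
    "SyntheticSession",
    "ThresholdHuntResult",
    "generate_perturbation_signal",
    "generate_gait_kinematics",
    "generate_emg_with_meps",
    "generate_coil_displacement",
    "simulate_threshold_hunt",
    "generate_session",
    "default_config",
]

MUSCLES = (
    "adductor_magnus",
    "biceps_femoris",
    "gluteus_medius",
    "rectus_femoris",
    "tibialis_anterior",
    "gastrocnemius_medialis",
    "gastrocnemius_lateralis",
)

#: Phasic activity envelopes, per muscle: (centre %, width %, amplitude uV)
#: bumps over the gait cycle (0% = right heel strike), roughly following
#: the textbook activation phases of treadmill walking.
DEFAULT_ENVELOPES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "adductor_magnus": ((95.0, 10.0, 80.0),),
    "biceps_femoris": ((90.0, 8.0, 100.0),),
    "gluteus_medius": ((10.0, 10.0, 110.0),),
    "rectus_femoris": ((5.0, 8.0, 90.0), (60.0, 6.0, 60.0)),
    "tibialis_anterior": ((0.0, 6.0, 120.0), (60.0, 8.0, 80.0)),
    "gastrocnemius_medialis": ((40.0, 8.0, 150.0),),
    "gastrocnemius_lateralis": ((40.0, 8.0, 120.0),),
}
ENVELOPE_BASELINE_UV = 8.0
DEFAULT_MEP_GAIN = 6.0  # dimensionless gain over pre-stimulus activity

# heel-height template: small stance lift so the per-cycle minimum is
# unique at heel strike, a broad swing-clearance bump, and a sharper
# heel-off rise whose leading-edge curvature maximum places toe-off at a
# realistic ~67% of the cycle; shape is a free design choice
_TEMPLATE_LIFT_MM = 2.0
_TEMPLATE_SWING_MM = 55.0
_TEMPLATE_SWING_KAPPA = 10.0
_TEMPLATE_SWING_CENTRE = 0.74
_TEMPLATE_RISE_MM = 25.0
_TEMPLATE_RISE_KAPPA = 50.0
_TEMPLATE_RISE_CENTRE = 0.63

# fraction of the belt displacement transmitted to the pelvis-relative
# CoM state (the body partially rides the oscillating surface)
_PERT_COUPLING = 0.3
_THORAX_PERT_COUPLING = 0.4

MEP_ONSET_MS = 12.0
MEP_PERIOD_MS = 8.0
MEP_DECAY_MS = 15.0


def _rng(seed: int, *names: str) -> np.random.Generator:
    """Deterministic named child stream of a root seed."""
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *keys])


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition generator settings (defaults = steady-state gait)."""

    stride_duration_mean: float = 1.10  # s
    stride_duration_sd: float = 0.02  # s
    step_width_mean: float = 100.0  # mm
    step_width_sd: float = 5.0  # mm, placement noise independent of CoM state
    perturbation_peak_to_peak: float = 0.0  # mm
    com_deviation_sd: float = 8.0  # mm, band-limited CoM deviation process
    thorax_noise_sd: float = 3.0  # mm
    emg_scale: float = 1.0  # multiplies activity envelopes
    gain_effect: tuple[float, float, float] | None = None  # (centre %, halfwidth %, factor)

    def validate(self) -> None:
        if self.stride_duration_mean <= 0:
            raise ValueError("stride_duration_mean must be positive")
        for name in ("stride_duration_sd", "step_width_sd", "com_deviation_sd",
                     "thorax_noise_sd", "perturbation_peak_to_peak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def destabilised_params() -> ConditionParams:
    """Default laterally destabilised condition: 100 mm peak-to-peak belt
    oscillation, shorter and more variable strides, wider and more
    variable steps, larger CoM deviations."""
    return ConditionParams(
        stride_duration_mean=1.05,
        stride_duration_sd=0.045,
        step_width_mean=120.0,
        step_width_sd=9.0,
        perturbation_peak_to_peak=100.0,
        com_deviation_sd=14.0,
        thorax_noise_sd=6.0,
        emg_scale=1.2,
    )


@dataclass(frozen=True)
class SessionConfig:
    """Full configuration of a synthetic session."""

    n_participants: int = 15
    trial_duration: float = 1200.0  # s (20-min trial)
    marker_rate: float = 100.0  # Hz
    emg_rate: float = 2000.0  # Hz
    belt_speed: float = 4.0  # km/h
    beta_position: float = 1.2  # mm per mm
    beta_velocity: float = 0.15  # mm per mm/s
    epsilon_sd: float = 5.0  # mm, residual of the placement law
    stim_stride_gap: tuple[int, int] = (3, 5)  # strides between pulses
    coil_exceedance_rate: float = 0.0
    emg_noise: float = 1.0  # scales the multiplicative EMG noise
    mep_amplitude_jitter: float = 0.1  # relative SD of injected amplitudes
    artifact_amplitude: float = 2000.0  # uV spike at the stimulation sample
    mep_gain: float = DEFAULT_MEP_GAIN
    rng_seed: int = 0
    conditions: dict[str, ConditionParams] = field(
        default_factory=lambda: {
            "steady": ConditionParams(),
            "destabilised": destabilised_params(),
        }
    )

    def validate(self) -> None:
        if self.marker_rate <= 0 or self.emg_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        lo, hi = self.stim_stride_gap
        if not (1 <= lo <= hi <= 20):
            raise ValueError("stim_stride_gap must lie within [1, 20]")
        if not 0.0 <= self.coil_exceedance_rate <= 1.0:
            raise ValueError("coil_exceedance_rate must lie in [0, 1]")
        if self.epsilon_sd < 0:
            raise ValueError("epsilon_sd must be non-negative")
        for params in self.conditions.values():
            params.validate()


@dataclass
class MarkerTimeSeries:
    """Labelled 3-D marker trajectories at a fixed rate (mm, lab frame).

    ``data`` columns follow the ``<MARKER>_<axis>`` convention with axes
    x (mediolateral), y (anteroposterior), z (vertical).
    """

    data: pd.DataFrame
    rate: float

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.data)) / self.rate

    def marker(self, name: str) -> np.ndarray:
        return self.data[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy()


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the analysis must recover."""

    condition: str
    hs_left: np.ndarray
    hs_right: np.ndarray
    to_left: np.ndarray
    to_right: np.ndarray
    steps: pd.DataFrame  # per-step: time, side, placement, state, noise terms
    beta_position: float
    beta_velocity: float
    epsilon_sd: float
    step_width_sd: float
    stim_times: np.ndarray | None = None
    stim_truth: pd.DataFrame | None = None  # per-stim: pct + true amplitudes

    def __post_init__(self) -> None:
        for name in ("hs_left", "hs_right", "to_left", "to_right"):
            if np.any(np.diff(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class SyntheticSession:
    config: SessionConfig
    condition: str
    markers: MarkerTimeSeries
    emg: pd.DataFrame  # time + one column per muscle, uV
    truth: SyntheticGroundTruth
    perturbation: np.ndarray  # mm, at marker rate
    coil_vertical: np.ndarray  # mm per stimulation
    coil_horizontal: np.ndarray


def default_config(**overrides) -> SessionConfig:
    cfg = SessionConfig(**overrides)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# perturbation signal
# ---------------------------------------------------------------------------

def generate_perturbation_signal(
    duration: float,
    rate: float,
    peak_to_peak: float,
    seed: int,
    n_components: int = 12,
    band: tuple[float, float] = (0.1, 1.0),
) -> np.ndarray:
    """Pseudorandom band-limited mediolateral belt displacement (mm).

    A sum of sinusoids with random incommensurate frequencies in ``band``
    and random phases, rescaled so max - min equals ``peak_to_peak``
    exactly and centred on its midrange (mean approximately zero).  The
    same seed always yields the same signal.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if peak_to_peak < 0:
        raise ValueError("peak_to_peak must be non-negative")
    n = int(round(duration * rate))
    if peak_to_peak == 0:
        return np.zeros(n)
    rng = _rng(seed, "perturbation")
    freqs = rng.uniform(band[0], band[1], size=n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
    amps = rng.uniform(0.5, 1.0, size=n_components)
    t = np.arange(n) / rate
    x = np.sum(
        amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    lo, hi = x.min(), x.max()
    z = (x - lo) / (hi - lo)  # exact 0 at argmin, exact 1 at argmax
    return peak_to_peak * (z - z.mean())


# ---------------------------------------------------------------------------
# heel-height template
# ---------------------------------------------------------------------------

def _heel_template(phi: np.ndarray) -> np.ndarray:
    """Heel height (mm) as a function of cycle phase in [0, 1).

    A small ``1 - cos`` stance lift makes the per-cycle minimum unique at
    phase 0 (heel strike); a broad Von Mises-shaped swing-clearance bump
    and a sharper heel-off rise shape the swing, and the template's
    global upward-acceleration maximum (on the rise's leading edge)
    defines the true toe-off.
    """
    lift = _TEMPLATE_LIFT_MM * (1.0 - np.cos(2.0 * np.pi * phi))
    swing = _TEMPLATE_SWING_MM * np.exp(
        _TEMPLATE_SWING_KAPPA
        * (np.cos(2.0 * np.pi * (phi - _TEMPLATE_SWING_CENTRE)) - 1.0)
    )
    rise = _TEMPLATE_RISE_MM * np.exp(
        _TEMPLATE_RISE_KAPPA
        * (np.cos(2.0 * np.pi * (phi - _TEMPLATE_RISE_CENTRE)) - 1.0)
    )
    return lift + swing + rise


def _template_toe_off_phase() -> float:
    """Phase of the template's maximal upward acceleration (= true toe-off)."""
    phi = np.linspace(0.0, 1.0, 20001)[:-1]
    z = _heel_template(phi)
    acc = np.gradient(np.gradient(z, phi), phi)
    return float(phi[np.argmax(acc)])


_TOE_OFF_PHASE = _template_toe_off_phase()


def _warp_template(t: np.ndarray, hs_times: np.ndarray) -> np.ndarray:
    """Evaluate the heel template on a piecewise-warped cycle clock."""
    k = np.clip(np.searchsorted(hs_times, t, side="right") - 1, 0, len(hs_times) - 2)
    t0 = hs_times[k]
    dur = hs_times[k + 1] - hs_times[k]
    phi = (t - t0) / dur
    # before the first / after the last heel strike: continue periodically
    phi = np.mod(phi, 1.0)
    return _heel_template(phi)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _bandlimited_process(
    n: int, rate: float, sd: float, cutoff: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean low-passed Gaussian process rescaled to the target SD."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n + int(4 * rate))  # burn-in pad
    sos = signal.butter(2, cutoff, btype="low", fs=rate, output="sos")
    x = signal.sosfilt(sos, white)[int(4 * rate) :]
    x = x - x.mean()
    return x * (sd / x.std())


def _smooth_process(
    n: int,
    rate: float,
    sd: float,
    rng: np.random.Generator,
    band: tuple[float, float] = (0.1, 1.2),
    n_components: int = 24,
) -> np.ndarray:
    """Smooth (infinitely differentiable) random multi-sine process.

    Used for the CoM deviation so that finite-difference velocities are
    well defined down to the sample level: sample-path derivatives of
    filtered white noise are too rough for the stored velocity truth and
    a discrete re-derivative to agree.
    """
    if sd == 0:
        return np.zeros(n)
    freqs = rng.uniform(band[0], band[1], size=n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_components)
    amps = rng.uniform(0.5, 1.0, size=n_components)
    t = np.arange(n) / rate
    x = np.sum(
        amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
        axis=0,
    )
    x = x - x.mean()
    return x * (sd / x.std())


def generate_gait_kinematics(
    config: SessionConfig,
    condition: str = "steady",
    seed: int | None = None,
    perturbation: np.ndarray | None = None,
) -> tuple[MarkerTimeSeries, SyntheticGroundTruth, np.ndarray]:
    """Synthesise marker kinematics and the matching ground truth.

    Construction (mediolateral axis, mm, + = right):

    * right heel strikes at cumulative Gaussian stride durations, left
      heel strikes mid-cycle; all event times quantised to the marker
      sample grid so stored truth coincides with what sampled data can
      express;
    * heel heights from the warped periodic template (per-cycle minimum
      at heel strike, acceleration maximum at toe-off);
    * a band-limited CoM deviation process ``dev(t)``; the true
      foot-placement state of each step combines ``dev`` with the partial
      belt coupling, oriented away from the stance foot, demeaned per side;
    * foot contacts chained: each placement sits one step width plus the
      control-law response away from the previous contact;
    * the pelvis rides from contact to contact with zero relative lateral
      velocity at contact, plus ``dev`` and the (inertia-lagged) belt
      displacement; thorax markers add stride-locked sway, belt coupling
      and their own noise.

    Returns ``(markers, truth, perturbation)``.
    """
    config.validate()
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    params = config.conditions[condition]
    if seed is None:
        seed = config.rng_seed
    rate = config.marker_rate
    dt = 1.0 / rate
    duration = config.trial_duration
    n = int(round(duration * rate))
    t = np.arange(n) * dt

    rng_strides = _rng(seed, condition, "strides")
    rng_dev = _rng(seed, condition, "com-deviation")
    rng_place = _rng(seed, condition, "placement")
    rng_thorax = _rng(seed, condition, "thorax")

    # --- stride sequence, quantised to the marker grid ---
    n_strides_max = int(np.ceil(duration / params.stride_duration_mean)) + 4
    durs = rng_strides.normal(
        params.stride_duration_mean, params.stride_duration_sd, size=n_strides_max
    )
    durs = np.clip(durs, 0.5, params.stride_duration_mean + 4 * params.stride_duration_sd + 0.1)
    durs = np.round(durs * rate) / rate
    hs_right = np.round(1.0 * rate) / rate + np.concatenate([[0.0], np.cumsum(durs)])
    hs_right = hs_right[hs_right <= duration - 1.0 - dt]
    if len(hs_right) < 3:
        raise ValueError("trial too short for gait synthesis")
    stride_durs = np.diff(hs_right)
    hs_left = np.round((hs_right[:-1] + 0.5 * stride_durs) * rate) / rate
    to_right = np.round((hs_right[:-1] + _TOE_OFF_PHASE * stride_durs) * rate) / rate
    # left cycles run heel-strike to heel-strike of the left foot
    left_durs = np.diff(hs_left)
    to_left = np.round((hs_left[:-1] + _TOE_OFF_PHASE * left_durs) * rate) / rate

    # --- heel heights ---
    lhee_z = _warp_template(t, hs_left)
    rhee_z = _warp_template(t, hs_right)

    # --- perturbation and CoM deviation ---
    if perturbation is None:
        perturbation = generate_perturbation_signal(
            duration, rate, params.perturbation_peak_to_peak, seed
        )
    pert = np.asarray(perturbation, dtype=float)
    if len(pert) != n:
        raise ValueError("perturbation length must match the marker clock")
    pert_vel = np.gradient(pert, dt)
    dev = _smooth_process(n, rate, params.com_deviation_sd, rng_dev)
    dev_vel = np.gradient(dev, dt)

    # true per-step CoM states: position includes the belt fraction the
    # body does not follow; velocity includes the belt velocity the
    # analysis adds back
    state_pos_raw = dev - _PERT_COUPLING * pert
    state_vel_raw = dev_vel + (1.0 - _PERT_COUPLING) * pert_vel

    # --- chronological step sequence (side alternation) ---
    events = sorted(
        [(float(tt), "right") for tt in hs_right] + [(float(tt), "left") for tt in hs_left]
    )
    step_times = np.array([e[0] for e in events])
    step_sides = np.array([e[1] for e in events])
    signs = np.where(step_sides == "right", 1.0, -1.0)
    idx = np.round(step_times * rate).astype(int)

    pos_states = signs * state_pos_raw[idx]
    vel_states = signs * state_vel_raw[idx]
    # demean within side (the placement law acts on deviations)
    for side in ("left", "right"):
        m = step_sides == side
        pos_states[m] -= pos_states[m].mean()
        vel_states[m] -= vel_states[m].mean()

    eps = rng_place.normal(0.0, config.epsilon_sd, size=len(step_times))
    eta = rng_place.normal(0.0, params.step_width_sd, size=len(step_times))
    d = config.beta_position * pos_states + config.beta_velocity * vel_states + eps + eta

    # chain contacts: first two feet around the origin, then the law
    contacts = np.empty(len(step_times))
    contacts[0] = signs[0] * params.step_width_mean / 2.0
    for j in range(1, len(step_times)):
        contacts[j] = contacts[j - 1] + signs[j] * (params.step_width_mean + d[j])

    # heel ML trajectories: piecewise constant at the latest contact
    # (sample comparisons in integer indices; the contact sample itself
    # already shows the new placement)
    samples = np.arange(n)
    lhee_x = np.empty(n)
    rhee_x = np.empty(n)
    for heel, side in ((lhee_x, "left"), (rhee_x, "right")):
        m = step_sides == side
        idx_s, contacts_s = idx[m], contacts[m]
        k = np.clip(np.searchsorted(idx_s, samples, side="right") - 1, 0, len(idx_s) - 1)
        heel[:] = contacts_s[k]

    # --- pelvis ---
    # base path rides from the previous contact one nominal step width
    # toward the swing side, with zero lateral velocity at contact; the
    # placement response d enters the feet only, so the relative pelvis
    # state at heel strike is exactly the stored CoM state.  The
    # heel-strike sample itself belongs to the step it terminates, so the
    # state at contact is free of the base-path jump to the new stance
    # foot (the jump lands between the contact sample and the next).
    j0 = np.clip(np.searchsorted(idx, samples, side="left") - 1, 0, len(step_times) - 2)
    t_a = step_times[j0]
    t_b = step_times[j0 + 1]
    phi = np.clip((t - t_a) / (t_b - t_a), 0.0, 1.0)
    base_from = contacts[j0]
    swing_sign = signs[np.minimum(j0 + 1, len(signs) - 1)]
    g = swing_sign * params.step_width_mean * (1.0 - np.cos(np.pi * phi)) / 2.0
    pelvis = base_from + g + dev - _PERT_COUPLING * pert

    # --- thorax ---
    k = np.clip(np.searchsorted(hs_right, t, side="right") - 1, 0, len(hs_right) - 2)
    phi_stride = np.mod((t - hs_right[k]) / (hs_right[k + 1] - hs_right[k]), 1.0)
    thorax_noise = _bandlimited_process(n, rate, params.thorax_noise_sd, 2.0, rng_thorax)
    thorax_ml = (
        25.0 * np.sin(2.0 * np.pi * phi_stride)
        + _THORAX_PERT_COUPLING * pert
        + thorax_noise
        + 0.5 * dev
    )
    bob = 15.0 * np.cos(4.0 * np.pi * phi_stride)  # double-bounce vertical

    zeros = np.zeros(n)
    data = pd.DataFrame(
        {
            "time": t,
            "LHEE_x": lhee_x, "LHEE_y": zeros, "LHEE_z": lhee_z,
            "RHEE_x": rhee_x, "RHEE_y": zeros, "RHEE_z": rhee_z,
            "LPSI_x": pelvis - 60.0, "LPSI_y": zeros - 150.0, "LPSI_z": 1000.0 + bob,
            "RPSI_x": pelvis + 60.0, "RPSI_y": zeros - 150.0, "RPSI_z": 1000.0 + bob,
            "C7_x": thorax_ml, "C7_y": zeros - 100.0, "C7_z": 1450.0 + bob,
            "LSHO_x": thorax_ml - 180.0, "LSHO_y": zeros - 80.0, "LSHO_z": 1420.0 + bob,
            "RSHO_x": thorax_ml + 180.0, "RSHO_y": zeros - 80.0, "RSHO_z": 1420.0 + bob,
        }
    )

    steps = pd.DataFrame(
        {
            "time": step_times,
            "side": step_sides,
            "contact_ml": contacts,
            "state_position": pos_states,
            "state_velocity": vel_states,
            "epsilon": eps,
            "eta": eta,
            "placement_deviation": d,
        }
    )
    truth = SyntheticGroundTruth(
        condition=condition,
        hs_left=hs_left,
        hs_right=hs_right,
        to_left=to_left,
        to_right=to_right,
        steps=steps,
        beta_position=config.beta_position,
        beta_velocity=config.beta_velocity,
        epsilon_sd=config.epsilon_sd,
        step_width_sd=params.step_width_sd,
    )
    return MarkerTimeSeries(data=data, rate=rate), truth, pert


# ---------------------------------------------------------------------------
# EMG + MEPs
# ---------------------------------------------------------------------------

def _envelope(pct: np.ndarray, bumps, scale: float) -> np.ndarray:
    """Phasic activity envelope (uV rectified-mean) at cycle percentages."""
    pct = np.asarray(pct, dtype=float)
    out = np.full(pct.shape, ENVELOPE_BASELINE_UV)
    for centre, width, amp in bumps:
        kappa = (100.0 / (2.0 * np.pi * width)) ** 2
        out = out + amp * np.exp(
            kappa * (np.cos(2.0 * np.pi * (pct - centre) / 100.0) - 1.0)
        )
    return scale * out


def _gain_profile(pct: np.ndarray, base_gain: float, effect) -> np.ndarray:
    """MEP gain over the cycle, with an optional injected cyclic-window effect."""
    pct = np.asarray(pct, dtype=float)
    g = np.full(pct.shape, base_gain)
    if effect is not None:
        centre, halfwidth, factor = effect
        dist = np.abs(pct - centre) % 100.0
        dist = np.minimum(dist, 100.0 - dist)
        g = np.where(dist <= halfwidth, g * factor, g)
    return g


def _mep_waveform(rate: float) -> np.ndarray:
    """Unit damped-sinusoid MEP template (8 ms period, 15 ms decay)."""
    tt = np.arange(0.0, 0.06, 1.0 / rate)
    w = np.sin(2.0 * np.pi * tt / (MEP_PERIOD_MS / 1000.0)) * np.exp(
        -tt / (MEP_DECAY_MS / 1000.0)
    )
    return w / (w.max() - w.min())  # unit peak-to-peak


def _cycle_pct_of(times: np.ndarray, hs_right: np.ndarray) -> np.ndarray:
    k = np.clip(np.searchsorted(hs_right, times, side="right") - 1, 0, len(hs_right) - 2)
    return 100.0 * (times - hs_right[k]) / (hs_right[k + 1] - hs_right[k])


def generate_emg_with_meps(
    config: SessionConfig,
    condition: str,
    truth: SyntheticGroundTruth,
    seed: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Synthesise EMG traces with scheduled TMS pulses and injected MEPs.

    Each muscle's trace is its phasic envelope (a function of gait-cycle
    percentage) multiplied by band-limited noise whose rectified mean is
    one, so the rectified-mean ongoing EMG recovers the envelope.  Pulses
    are scheduled 3-5 strides apart at a uniformly random delay after a
    right heel strike; at each pulse a damped-sinusoid MEP with
    peak-to-peak amplitude ``gain(cycle %) x envelope(cycle %)`` (plus
    relative jitter) is added 12 ms after the stimulation sample, along
    with an artifact spike at the stimulation sample itself.

    Returns ``(emg_frame, stim_times, stim_truth)`` where ``stim_truth``
    holds each pulse's cycle percentage and true per-muscle amplitudes.
    """
    config.validate()
    params = config.conditions[condition]
    if seed is None:
        seed = config.rng_seed
    rate = config.emg_rate
    hs = truth.hs_right
    if hs[-1] < config.trial_duration - 10.0 - params.stride_duration_mean * 6:
        raise ValueError("ground-truth events do not cover the trial duration")
    n = int(round(config.trial_duration * rate))
    t = np.arange(n) / rate
    pct_t = _cycle_pct_of(np.clip(t, hs[0], hs[-1]), hs)

    # --- stimulation schedule ---
    rng_sched = _rng(seed, condition, "stim-schedule")
    lo, hi = config.stim_stride_gap
    stim_times = []
    i = int(rng_sched.integers(lo, hi + 1))
    while i < len(hs) - 1:
        delay = rng_sched.uniform(0.0, hs[i + 1] - hs[i])
        st = round((hs[i] + delay) * rate) / rate
        if hs[0] < st < hs[-1] and st < config.trial_duration - 0.1:
            stim_times.append(st)
        i += int(rng_sched.integers(lo, hi + 1))
    stim_times = np.asarray(stim_times)
    stim_idx = np.round(stim_times * rate).astype(int)
    stim_pct = _cycle_pct_of(stim_times, hs)

    wave = _mep_waveform(rate)
    onset = int(round(MEP_ONSET_MS / 1000.0 * rate))

    emg = {"time": t}
    truth_cols: dict[str, np.ndarray] = {"stim_time": stim_times, "cycle_pct": stim_pct}
    for muscle in MUSCLES:
        rng_m = _rng(seed, condition, "emg", muscle)
        env = _envelope(pct_t, DEFAULT_ENVELOPES[muscle], params.emg_scale)
        if config.emg_noise > 0:
            white = rng_m.standard_normal(n + int(rate))
            sos = signal.butter(2, [20.0, 450.0], btype="bandpass", fs=rate, output="sos")
            noise = signal.sosfilt(sos, white)[int(rate) :]
            noise /= np.mean(np.abs(noise))  # unit rectified mean
            x = env * config.emg_noise * noise
        else:
            x = np.zeros(n)
        env_at_stim = _envelope(stim_pct, DEFAULT_ENVELOPES[muscle], params.emg_scale)
        gains = _gain_profile(stim_pct, config.mep_gain, params.gain_effect)
        jitter = 1.0 + config.mep_amplitude_jitter * rng_m.standard_normal(len(stim_times))
        amps = np.maximum(gains * env_at_stim * np.maximum(jitter, 0.0), 0.0)
        for st_i, amp in zip(stim_idx, amps):
            a = st_i + onset
            b = min(a + len(wave), n)
            x[a:b] += amp * wave[: b - a]
            if config.artifact_amplitude:
                x[st_i] += config.artifact_amplitude
        emg[muscle] = x
        truth_cols[f"amp_{muscle}"] = amps
        truth_cols[f"gain_{muscle}"] = gains
        truth_cols[f"ongoing_{muscle}"] = env_at_stim
    return pd.DataFrame(emg), stim_times, pd.DataFrame(truth_cols)


# ---------------------------------------------------------------------------
# coil displacement
# ---------------------------------------------------------------------------

def generate_coil_displacement(
    config: SessionConfig, n_stimulations: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stimulation coil displacement (vertical, horizontal; mm).

    Baseline displacements sit safely below the 5 mm vertical / 10 mm
    horizontal exclusion thresholds; each pulse independently exceeds a
    randomly chosen threshold with probability ``coil_exceedance_rate``.
    """
    config.validate()
    if seed is None:
        seed = config.rng_seed
    rng = _rng(seed, "coil")
    vertical = np.minimum(np.abs(rng.normal(0.0, 1.2, n_stimulations)), 4.5)
    horizontal = np.minimum(np.abs(rng.normal(0.0, 2.5, n_stimulations)), 9.5)
    exceed = rng.random(n_stimulations) < config.coil_exceedance_rate
    which_vertical = rng.random(n_stimulations) < 0.5
    bump_v = 5.0 + np.abs(rng.normal(2.0, 1.0, n_stimulations)) + 1e-6
    bump_h = 10.0 + np.abs(rng.normal(3.0, 1.5, n_stimulations)) + 1e-6
    vertical = np.where(exceed & which_vertical, bump_v, vertical)
    horizontal = np.where(exceed & ~which_vertical, bump_h, horizontal)
    return vertical, horizontal


# ---------------------------------------------------------------------------
# motor-threshold staircase
# ---------------------------------------------------------------------------

@dataclass
class ThresholdHuntResult:
    threshold: float | None  # % maximal stimulator output
    test_intensity: float | None  # 110% of threshold
    terminated: bool


def simulate_threshold_hunt(
    recruitment,
    seed: int = 0,
    start: float = 35.0,
    ceiling: float = 100.0,
    n_trials: int = 10,
    criterion: int = 5,
) -> ThresholdHuntResult:
    """Simulate the motor-threshold staircase.

    ``recruitment(intensity)`` gives the probability of observing an MEP
    at that stimulator intensity (monotone non-decreasing).  The hunt
    starts at 35% of maximal output, increases in 5% steps until an MEP
    is seen in at least 5 of 10 pulses (if the criterion already holds at
    the start, the start is the threshold), then decreases in 2% steps
    until the criterion fails, then increases in 1% steps to the lowest
    intensity that consistently evokes an MEP.  If the ceiling is reached
    without reaching criterion, the hunt is terminated (session aborted).
    The experimental test intensity is 110% of the threshold.
    """
    rng = _rng(seed, "threshold-hunt")

    def criterion_met(intensity: float) -> bool:
        p = float(recruitment(intensity))
        if not 0.0 <= p <= 1.0:
            raise ValueError("recruitment must return a probability")
        return int((rng.random(n_trials) < p).sum()) >= criterion

    intensity = start
    if not criterion_met(intensity):
        while True:
            intensity += 5.0
            if intensity > ceiling:
                return ThresholdHuntResult(None, None, True)
            if criterion_met(intensity):
                break
        while intensity > 1.0 and criterion_met(intensity - 2.0):
            intensity -= 2.0
        # criterion fails at intensity - 2; climb in 1% steps
        probe = intensity - 2.0
        while probe < intensity:
            probe += 1.0
            if criterion_met(probe):
                intensity = probe
                break
    return ThresholdHuntResult(intensity, 1.1 * intensity, False)


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------

def generate_session(
    config: SessionConfig, condition: str, seed: int | None = None
) -> SyntheticSession:
    """Generate one participant-condition session with full ground truth."""
    if seed is None:
        seed = config.rng_seed
    markers, truth, pert = generate_gait_kinematics(config, condition, seed)
    emg, stim_times, stim_truth = generate_emg_with_meps(config, condition, truth, seed)
    truth.stim_times = stim_times
    truth.stim_truth = stim_truth
    vert, horz = generate_coil_displacement(config, len(stim_times), seed)
    return SyntheticSession(
        config=config,
        condition=condition,
        markers=markers,
        emg=emg,
        truth=truth,
        perturbation=pert,
        coil_vertical=vert,
        coil_horizontal=horz,
    )
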