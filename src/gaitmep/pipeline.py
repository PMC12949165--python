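"""End-to-end orchestration, file formats and configuration.

Sequences the full analysis for a set of participants recorded in two
conditions (steady-state and laterally destabilised treadmill gait):
gait events -> spatiotemporal metrics -> local divergence exponent ->
foot-placement regression -> per-stimulation EMG/MEP extraction ->
cyclic smoothing -> scalar paired t tests and cyclic cluster-based
permutation tests.  Also defines the package's plain-text interchange
formats: wide CSV for markers (metres on disk, millimetres in memory)
and EMG, JSON for events, per-stimulation records, clusters and result
bundles, YAML for configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_stats, cyclic_smoothing, emg_mep, foot_placement, gait_events, stability
from .synthetic import (
    MUSCLES,
    MarkerTimeSeries,
    SessionConfig,
    SyntheticSession,
    generate_session,
)

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "analyze_session",
    "run_pipeline",
    "save_markers_csv",
    "load_markers_csv",
    "save_emg_csv",
    "load_emg_csv",
    "save_events_json",
    "load_events_json",
]

logger = logging.getLogger("gaitmep")

OUTCOMES = ("ongoing_emg", "absolute_mep", "mep_gain")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis constants; defaults are the study's fixed choices."""

    grid_resolution: float = 0.5  # % of gait cycle
    sigma_pct: float = 2.0  # Gaussian-equivalent kernel width, % of cycle
    kappa: float = 60.0  # Von Mises concentration
    min_density_count: int = 6
    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    vertical_threshold_mm: float = 5.0
    horizontal_threshold_mm: float = 10.0
    min_stims_per_condition: int = 100
    lambda_fit_window: tuple[float, float] = (0.0, 0.5)  # strides
    stability_n_strides: int = 150
    stability_delay: int = 10
    samples_per_stride: int = 100
    spatiotemporal_window: int = 150  # strides
    n_phase_points: int = 51
    averaging_mode: str = "weighted"  # or "unweighted"

    def validate(self) -> None:
        if 100.0 % self.grid_resolution > 1e-9:
            raise ValueError("grid_resolution must divide 100")
        for name in ("sigma_pct", "kappa", "alpha", "vertical_threshold_mm",
                     "horizontal_threshold_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "lambda_fit_window" in raw:
            raw["lambda_fit_window"] = tuple(raw["lambda_fit_window"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["lambda_fit_window"] = list(d["lambda_fit_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class ParticipantConditionResult:
    participant: int
    condition: str
    spatiotemporal: gait_events.SpatiotemporalSummary
    lambda_s: float
    fp_fit: foot_placement.FootPlacementFit
    records: pd.DataFrame  # one row per included stimulation
    participant_included: bool
    smoothed: dict[str, dict[str, cyclic_smoothing.SmoothedCyclicSeries]]


@dataclass
class ResultsBundle:
    config: AnalysisConfig
    participants: list[ParticipantConditionResult]
    scalar_tests: dict[str, dict]
    cluster_tests: dict[str, dict[str, object]]
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        out = {
            "provenance": self.provenance,
            "scalar_tests": self.scalar_tests,
            "clusters": {
                outcome: {
                    muscle: [
                        {
                            "start_idx": int(c.indices[0]),
                            "end_idx": int(c.indices[-1]),
                            "start_pct": float(c.indices[0] * self.config.grid_resolution),
                            "size": c.size,
                            "sign": c.sign,
                            "mass": c.mass,
                            "p_value": c.p_value,
                        }
                        for c in res.clusters
                    ]
                    for muscle, res in per_muscle.items()
                }
                for outcome, per_muscle in self.cluster_tests.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# per-session analysis
# ---------------------------------------------------------------------------

def _thorax_ml_velocity(markers: MarkerTimeSeries) -> np.ndarray:
    ml = (
        markers.data["C7_x"].to_numpy()
        + markers.data["LSHO_x"].to_numpy()
        + markers.data["RSHO_x"].to_numpy()
    ) / 3.0
    return np.gradient(ml, 1.0 / markers.rate)


def analyze_session(
    session: SyntheticSession, config: AnalysisConfig, participant: int = 0
) -> ParticipantConditionResult:
    """Run the whole per-participant-condition analysis chain."""
    config.validate()
    markers = session.markers
    rate = markers.rate
    logger.info("participant %d / %s: gait events", participant, session.condition)
    events = gait_events.detect_events(
        markers.data["LHEE_z"].to_numpy(), markers.data["RHEE_z"].to_numpy(), rate
    )

    _, widths = gait_events.compute_step_width(
        markers.data["LHEE_x"].to_numpy(), markers.data["RHEE_x"].to_numpy(), events, rate
    )
    durations = gait_events.compute_stride_durations(events.hs_right)
    window = min(config.spatiotemporal_window, len(durations))
    spatio = gait_events.summarize_spatiotemporal(widths, durations, window)

    logger.info("participant %d / %s: local divergence exponent", participant, session.condition)
    n_strides = min(config.stability_n_strides, len(events.hs_right) - 1)
    lam, _ = stability.lambda_s_from_velocity(
        _thorax_ml_velocity(markers),
        events.hs_right,
        rate,
        n_strides,
        samples_per_stride=config.samples_per_stride,
        delay=config.stability_delay,
    )

    logger.info("participant %d / %s: foot placement", participant, session.condition)
    pelvis = (
        markers.data["LPSI_x"].to_numpy() + markers.data["RPSI_x"].to_numpy()
    ) / 2.0
    treadmill = session.perturbation if np.any(session.perturbation) else None
    fits = []
    for side in ("left", "right"):
        try:
            m = foot_placement.extract_step_cycles(
                pelvis,
                markers.data["LHEE_x"].to_numpy(),
                markers.data["RHEE_x"].to_numpy(),
                events,
                rate,
                treadmill_displacement=treadmill,
                side=side,
                n_phase=config.n_phase_points,
            )
            fits.append(foot_placement.fit_model(m))
        except ValueError as exc:  # pragma: no cover - degenerate sessions
            logger.warning("foot placement (%s side) failed: %s", side, exc)
    if not fits:
        raise RuntimeError("foot-placement stage failed on both sides")
    fp_fit = _average_fits(fits)

    logger.info("participant %d / %s: EMG / MEP extraction", participant, session.condition)
    records = _extract_records(session, config)
    surviving = records[records["included"]]
    participant_included = len(surviving) >= config.min_stims_per_condition

    grid = cyclic_smoothing.CyclicGrid(config.grid_resolution)
    smoothed: dict[str, dict[str, cyclic_smoothing.SmoothedCyclicSeries]] = {}
    for outcome in OUTCOMES:
        smoothed[outcome] = {}
        for muscle in MUSCLES:
            sub = surviving[surviving["muscle"] == muscle]
            smoothed[outcome][muscle] = cyclic_smoothing.smooth_participant(
                sub["cycle_pct"].to_numpy(),
                sub[outcome].to_numpy(),
                grid,
                config.kappa,
                sigma_pct=config.sigma_pct,
                min_count=config.min_density_count,
            )
    return ParticipantConditionResult(
        participant=participant,
        condition=session.condition,
        spatiotemporal=spatio,
        lambda_s=lam,
        fp_fit=fp_fit,
        records=records,
        participant_included=participant_included,
        smoothed=smoothed,
    )


def _average_fits(fits: list[foot_placement.FootPlacementFit]) -> foot_placement.FootPlacementFit:
    """Headline curves = mean of the per-side fits (coefficients share signs
    because each side's matrix is oriented away from its stance foot)."""
    if len(fits) == 1:
        return fits[0]
    f0, f1 = fits
    return foot_placement.FootPlacementFit(
        beta_position=(f0.beta_position + f1.beta_position) / 2,
        beta_velocity=(f0.beta_velocity + f1.beta_velocity) / 2,
        beta_position_se=(f0.beta_position_se + f1.beta_position_se) / 2,
        beta_velocity_se=(f0.beta_velocity_se + f1.beta_velocity_se) / 2,
        r_squared=(f0.r_squared + f1.r_squared) / 2,
        fisher=(f0.fisher + f1.fisher) / 2,
        residuals=np.vstack([f0.residuals, f1.residuals]),
        fp_error=float(np.sqrt((f0.fp_error**2 + f1.fp_error**2) / 2)),
        n_steps=f0.n_steps + f1.n_steps,
    )


def _extract_records(session: SyntheticSession, config: AnalysisConfig) -> pd.DataFrame:
    """Filter EMG and build the per-stimulation x muscle record table."""
    rate = float(session.emg["time"].diff().median() ** -1)
    events_hs = session.truth.hs_right
    filtered = {
        m: emg_mep.bandpass_filter(session.emg[m].to_numpy(), rate) for m in MUSCLES
    }
    rows = []
    for i, st in enumerate(session.truth.stim_times):
        pct = emg_mep.assign_cycle_percentage(st, events_hs)
        if pct is None:
            continue
        vert = float(session.coil_vertical[i])
        horz = float(session.coil_horizontal[i])
        included = not (
            vert > config.vertical_threshold_mm or horz > config.horizontal_threshold_mm
        )
        idx = int(round(st * rate))
        for muscle in MUSCLES:
            x = filtered[muscle]
            ongoing = emg_mep.compute_ongoing_emg(x, idx, rate)
            mep = emg_mep.compute_absolute_mep(x, idx, rate)
            rows.append(
                {
                    "stim_time": st,
                    "cycle_pct": pct,
                    "muscle": muscle,
                    "coil_vertical": vert,
                    "coil_horizontal": horz,
                    "included": included,
                    "ongoing_emg": ongoing,
                    "absolute_mep": mep,
                    "mep_gain": emg_mep.compute_mep_gain(mep, ongoing),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-level pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    session_config: SessionConfig,
    analysis_config: AnalysisConfig | None = None,
    conditions: tuple[str, str] = ("steady", "destabilised"),
) -> ResultsBundle:
    """Simulate-and-analyse a full study and run the group statistics.

    Deterministic given both configurations: participant ``p``'s session
    in each condition derives from child seed ``seed + p``.
    """
    cfg = analysis_config or AnalysisConfig()
    cfg.validate()
    session_config.validate()
    results: list[ParticipantConditionResult] = []
    for p in range(session_config.n_participants):
        for condition in conditions:
            session = generate_session(
                session_config, condition, seed=session_config.rng_seed + p
            )
            results.append(analyze_session(session, cfg, participant=p))

    by_cond = {c: [r for r in results if r.condition == c] for c in conditions}
    a, b = conditions

    scalar_tests = {}
    scalars = {
        "step_width_mean": lambda r: r.spatiotemporal.step_width_mean,
        "step_width_var": lambda r: r.spatiotemporal.step_width_var,
        "stride_duration_mean": lambda r: r.spatiotemporal.stride_duration_mean,
        "stride_duration_var": lambda r: r.spatiotemporal.stride_duration_var,
        "lambda_s": lambda r: r.lambda_s,
        "fp_error": lambda r: r.fp_fit.fp_error,
    }
    for name, getter in scalars.items():
        va = np.array([getter(r) for r in by_cond[a]])
        vb = np.array([getter(r) for r in by_cond[b]])
        t, df, p = cluster_stats.paired_t_scalar(va, vb)
        scalar_tests[name] = {
            "t": t, "df": df, "p": p,
            f"mean_{a}": float(va.mean()), f"mean_{b}": float(vb.mean()),
        }

    cluster_tests: dict[str, dict[str, object]] = {}
    rng = np.random.default_rng(cfg.seed)
    for outcome in OUTCOMES:
        cluster_tests[outcome] = {}
        for muscle in MUSCLES:
            curves_a = np.stack([r.smoothed[outcome][muscle].values for r in by_cond[a]])
            curves_b = np.stack([r.smoothed[outcome][muscle].values for r in by_cond[b]])
            weights = None
            if cfg.averaging_mode == "weighted":
                dens = np.stack(
                    [r.smoothed[outcome][muscle].density for r in by_cond[a]]
                ) + np.stack(
                    [r.smoothed[outcome][muscle].density for r in by_cond[b]]
                )
                weights = dens / dens.sum(axis=0, keepdims=True)
            cluster_tests[outcome][muscle] = cluster_stats.permutation_null(
                curves_a,
                curves_b,
                n_permutations=cfg.n_permutations,
                alpha=cfg.alpha,
                seed=int(rng.integers(2**31)),
                mode=cfg.averaging_mode,
                weights=weights,
            )

    bundle = ResultsBundle(
        config=cfg,
        participants=results,
        scalar_tests=scalar_tests,
        cluster_tests=cluster_tests,
        provenance={
            "config_hash": cfg.config_hash(),
            "seed": session_config.rng_seed,
            "n_participants": session_config.n_participants,
            "conditions": list(conditions),
        },
    )
    return bundle


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def save_markers_csv(markers: MarkerTimeSeries, path: str | Path) -> None:
    """Write markers as wide CSV in metres (time + <MARKER>_<axis> columns)."""
    out = markers.data.copy()
    for col in out.columns:
        if col != "time":
            out[col] = out[col] / 1000.0
    out.to_csv(path, index=False, float_format="%.9g")


def load_markers_csv(path: str | Path) -> MarkerTimeSeries:
    """Read a wide marker CSV (metres) into millimetre trajectories."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: marker CSV must contain a 'time' column")
    rate = 1.0 / float(np.median(np.diff(df["time"].to_numpy())))
    for col in df.columns:
        if col != "time":
            df[col] = df[col] * 1000.0
    return MarkerTimeSeries(data=df, rate=round(rate, 6))


def save_emg_csv(emg: pd.DataFrame, path: str | Path) -> None:
    emg.to_csv(path, index=False, float_format="%.9g")


def load_emg_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: EMG CSV must contain a 'time' column")
    return df


def save_events_json(events: gait_events.GaitEvents, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {k: list(map(float, getattr(events, k)))
             for k in ("hs_left", "hs_right", "to_left", "to_right")},
            fh,
        )


def load_events_json(path: str | Path) -> gait_events.GaitEvents:
    with open(path) as fh:
        raw = json.load(fh)
    return gait_events.GaitEvents(**{k: np.asarray(v) for k, v in raw.items()})
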