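"""Take-off kinematics from center-of-mass tracking traces.

A trial is a time-stamped 2-D CoM track from high-speed video (the study
filmed at 6000 fps, 0.166 ms between frames) with two annotated events: the
first movement of a propulsive leg and the instant the last leg leaves the
ground. Take-off duration, velocity and acceleration derive from the track
between those events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import savgol_filter

from .types import ValidationError

__all__ = [
    "KinematicsTrial",
    "TakeoffMetrics",
    "takeoff_metrics",
    "average_trials",
    "TrialSummary",
    "read_trial",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KinematicsTrial:
    """One jump's CoM track plus contact-event annotations (SI units)."""

    times_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    first_movement_time_s: float
    last_contact_time_s: float
    frame_interval_s: float
    body_mass_kg: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.x_m, dtype=float)
        y = np.asarray(self.y_m, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1 and t.size == x.size == y.size):
            raise ValidationError("times, x and y must be aligned 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not (self.first_movement_time_s < self.last_contact_time_s):
            raise ValidationError("first movement must precede last contact")
        if self.first_movement_time_s < t[0] or self.last_contact_time_s > t[-1]:
            raise ValidationError("event times must lie within the track")
        inside = (t >= self.first_movement_time_s) & (t <= self.last_contact_time_s)
        if inside.sum() < 5:
            raise ValidationError(
                f"need >= 5 samples between the contact events, got {inside.sum()}"
            )
        if not (self.frame_interval_s > 0):
            raise ValidationError("frame_interval_s must be > 0")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "x_m", x)
        object.__setattr__(self, "y_m", y)


@dataclass(frozen=True)
class TakeoffMetrics:
    """Scalar take-off performance of one jump."""

    duration_s: float
    mean_velocity_m_s: float
    takeoff_velocity_m_s: float
    mean_acceleration_m_s2: float


def _nearest_index(times: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(times - t)))


def takeoff_metrics(trial: KinematicsTrial, smoothing_window: int = 5) -> TakeoffMetrics:
    """Derive take-off duration, velocity and acceleration from a trial.

    duration: last contact minus first movement.
    mean_velocity: net CoM displacement between the events over duration.
    takeoff_velocity: speed at last contact from a local-quadratic
    (Savitzky-Golay) smoothed derivative of the stance-phase track; only
    samples up to last contact enter the fit, because the motion model
    changes to ballistic flight afterwards. Exact for noise-free uniformly
    accelerated stance motion.
    mean_acceleration: takeoff_velocity / duration.

    ``smoothing_window`` is an odd sample count; 5 suits clean tracks, wider
    windows (e.g. 21, ~3.5 ms at 6000 fps) suppress tracking noise.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValidationError("smoothing_window must be odd and >= 1")
    t = trial.times_s
    i0 = _nearest_index(t, trial.first_movement_time_s)
    i1 = _nearest_index(t, trial.last_contact_time_s)
    duration = trial.last_contact_time_s - trial.first_movement_time_s
    disp = np.hypot(trial.x_m[i1] - trial.x_m[i0], trial.y_m[i1] - trial.y_m[i0])
    mean_velocity = float(disp / duration)

    n_stance = i1 - i0 + 1
    if smoothing_window > n_stance:
        raise ValidationError(
            f"smoothing_window {smoothing_window} exceeds the "
            f"{n_stance}-sample stance segment"
        )
    ts = t[i0 : i1 + 1]
    if smoothing_window < 3:
        # window 1: plain central differences, no smoothing
        vx = np.gradient(trial.x_m[i0 : i1 + 1], ts)
        vy = np.gradient(trial.y_m[i0 : i1 + 1], ts)
    else:
        dt = float(np.mean(np.diff(ts)))
        vx = savgol_filter(
            trial.x_m[i0 : i1 + 1], smoothing_window, polyorder=2,
            deriv=1, delta=dt, mode="interp",
        )
        vy = savgol_filter(
            trial.y_m[i0 : i1 + 1], smoothing_window, polyorder=2,
            deriv=1, delta=dt, mode="interp",
        )
    takeoff_velocity = float(np.hypot(vx[-1], vy[-1]))
    return TakeoffMetrics(
        duration_s=float(duration),
        mean_velocity_m_s=mean_velocity,
        takeoff_velocity_m_s=takeoff_velocity,
        mean_acceleration_m_s2=takeoff_velocity / duration,
    )


@dataclass(frozen=True)
class TrialSummary:
    """Mean and standard error of each take-off metric over repeat jumps."""

    n_trials: int
    mean: TakeoffMetrics
    sem: TakeoffMetrics


def average_trials(metrics: list[TakeoffMetrics]) -> TrialSummary:
    """Arithmetic mean +/- s.e. (sd/sqrt(n)) per metric over repeat jumps."""
    if not metrics:
        raise ValidationError("need at least one trial")
    n = len(metrics)
    if n == 1:
        logger.warning("single trial: standard errors reported as 0")
    names = [f.name for f in fields(TakeoffMetrics)]
    means, sems = {}, {}
    for name in names:
        values = np.array([getattr(m, name) for m in metrics], dtype=float)
        means[name] = float(values.mean())
        sems[name] = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return TrialSummary(n_trials=n, mean=TakeoffMetrics(**means), sem=TakeoffMetrics(**sems))


def read_trial(track_csv: str | Path, events_yaml: str | Path) -> KinematicsTrial:
    """Load a trial from a track CSV (time_s, x_m, y_m) and an events file.

    The YAML sidecar carries ``first_movement_time_s``, ``last_contact_time_s``,
    ``frame_interval_s`` and optionally ``body_mass_kg``.
    """
    df = pd.read_csv(track_csv, float_precision="round_trip")
    for col in ("time_s", "x_m", "y_m"):
        if col not in df.columns:
            raise ValidationError(f"{track_csv}: missing column {col}")
    with open(events_yaml, "r", encoding="utf-8") as fh:
        events = yaml.safe_load(fh) or {}
    try:
        return KinematicsTrial(
            times_s=df["time_s"].to_numpy(float),
            x_m=df["x_m"].to_numpy(float),
            y_m=df["y_m"].to_numpy(float),
            first_movement_time_s=float(events["first_movement_time_s"]),
            last_contact_time_s=float(events["last_contact_time_s"]),
            frame_interval_s=float(events["frame_interval_s"]),
            body_mass_kg=(
                float(events["body_mass_kg"]) if "body_mass_kg" in events else None
            ),
        )
    except KeyError as exc:
        raise ValidationError(f"{events_yaml}: missing event field {exc}") from exc
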