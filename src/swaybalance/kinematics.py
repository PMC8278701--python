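"""Angle reconstruction and hand-engineered sway descriptors.

Only angular velocity is recorded, so trunk angles are reconstructed by
cumulative trapezoidal integration followed by linear detrending (drift
suppression).  The descriptor set covers root-mean-square magnitude, sway
path length and 95% confidence-ellipse area, each computed in both the
angle (deg) and angular-velocity (deg/s) domains, per axis and as the
two-axis resultant — 11 named features in total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy.integrate import cumulative_trapezoid
from scipy.stats import chi2

from .data_model import SwayRecording

__all__ = [
    "SwayTrajectory",
    "FeatureVector",
    "FEATURE_NAMES",
    "integrate_angle",
    "rms",
    "resultant_rms",
    "path_length",
    "ellipse_area",
    "feature_vector",
]

FEATURE_NAMES: tuple[str, ...] = (
    "rms_pitch_angle",
    "rms_roll_angle",
    "rms_resultant_angle",
    "rms_pitch_velocity",
    "rms_roll_velocity",
    "rms_resultant_velocity",
    "path_length_angle",
    "path_length_velocity",
    "ellipse_area_angle",
    "ellipse_area_velocity",
    "rms_resultant_combined",
)


@dataclass(frozen=True)
class SwayTrajectory:
    """A 2-D pitch/roll trajectory in either the angle or velocity domain."""

    pitch: np.ndarray
    roll: np.ndarray
    kind: str  # "angle" | "velocity"

    def __post_init__(self) -> None:
        p = np.asarray(self.pitch, dtype=float)
        r = np.asarray(self.roll, dtype=float)
        object.__setattr__(self, "pitch", p)
        object.__setattr__(self, "roll", r)
        if p.shape != r.shape or p.ndim != 1:
            raise ValueError("pitch and roll must be equal-length 1-D arrays")
        if not (np.isfinite(p).all() and np.isfinite(r).all()):
            raise ValueError("trajectory contains non-finite samples")
        if self.kind not in ("angle", "velocity"):
            raise ValueError(f"kind must be 'angle' or 'velocity', got {self.kind!r}")

    def __len__(self) -> int:
        return int(self.pitch.size)

    def as_points(self) -> np.ndarray:
        """(n, 2) array of (pitch, roll) samples."""
        return np.column_stack([self.pitch, self.roll])


@dataclass(frozen=True)
class FeatureVector:
    """The 11 named kinematic descriptors for one repetition."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("features must be finite")
        if (v < 0).any():
            raise ValueError("features must be non-negative")

    def __len__(self) -> int:
        return int(self.values.size)

    def as_dict(self) -> dict[str, float]:
        return {name: float(val) for name, val in zip(FEATURE_NAMES, self.values)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def integrate_angle(rec: SwayRecording) -> SwayTrajectory:
    """Reconstruct trunk angles from angular velocity.

    Cumulative trapezoidal integration at the recording's sample period,
    then per-channel removal of the best-fit linear trend.  A constant
    velocity offset therefore integrates to a ramp that is removed exactly.
    """
    if rec.n_samples < 2:
        raise ValueError("need at least 2 samples to integrate")
    dt = 1.0 / rec.sample_rate
    pitch = cumulative_trapezoid(rec.pitch_velocity, dx=dt, initial=0.0)
    roll = cumulative_trapezoid(rec.roll_velocity, dx=dt, initial=0.0)
    pitch = sp_signal.detrend(pitch, type="linear")
    roll = sp_signal.detrend(roll, type="linear")
    return SwayTrajectory(pitch=pitch, roll=roll, kind="angle")


def rms(values: Sequence[float] | np.ndarray) -> float:
    """Root-mean-square of a sequence."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("rms of an empty sequence is undefined")
    return float(np.sqrt(np.mean(v**2)))


def resultant_rms(pitch: Sequence[float] | np.ndarray, roll: Sequence[float] | np.ndarray) -> float:
    """RMS of the per-sample Euclidean magnitude sqrt(pitch^2 + roll^2).

    Algebraically equals ``sqrt(rms(pitch)^2 + rms(roll)^2)`` and is
    invariant under joint rotation of the two axes.
    """
    p = np.asarray(pitch, dtype=float)
    r = np.asarray(roll, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {r.shape}")
    if p.size == 0:
        raise ValueError("resultant_rms of empty sequences is undefined")
    return float(np.sqrt(np.mean(p**2 + r**2)))


def path_length(traj: SwayTrajectory) -> float:
    """Cumulative Euclidean distance travelled across consecutive samples."""
    if len(traj) < 2:
        return 0.0
    dp = np.diff(traj.pitch)
    dr = np.diff(traj.roll)
    return float(np.sum(np.hypot(dp, dr)))


def ellipse_area(traj: SwayTrajectory, coverage: float = 0.95) -> float:
    """Area of the ``coverage``-level confidence ellipse of the 2-D samples.

    Computed as ``pi * q * sqrt(lambda1 * lambda2)`` where the lambdas are
    the eigenvalues of the sample covariance and ``q`` is the chi-square
    (2 df) quantile at ``coverage``.  Degenerate (rank < 2) point clouds
    yield 0 with a warning.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 samples for a covariance ellipse")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    cov = np.cov(traj.pitch, traj.roll)
    eigvals = np.linalg.eigvalsh(cov)
    if np.min(eigvals) <= 0:
        warnings.warn("degenerate sway covariance; ellipse area set to 0", stacklevel=2)
        return 0.0
    q = float(chi2.ppf(coverage, df=2))
    return float(np.pi * q * np.sqrt(eigvals[0] * eigvals[1]))


def _normalized_magnitude(pitch: np.ndarray, roll: np.ndarray) -> np.ndarray:
    """Per-sample resultant magnitude scaled to unit maximum (0 if flat)."""
    mag = np.hypot(pitch, roll)
    peak = float(np.max(mag))
    if peak == 0.0:
        return mag
    return mag / peak


def feature_vector(rec: SwayRecording, coverage: float = 0.95) -> FeatureVector:
    """Compute all 11 kinematic descriptors for one repetition.

    The combined entry is the RMS of the concatenated scale-normalized
    resultant magnitudes from the angle and velocity domains, capturing
    the joint shape of the two trajectories independent of amplitude.
    """
    angle = integrate_angle(rec)
    vel = SwayTrajectory(pitch=rec.pitch_velocity, roll=rec.roll_velocity, kind="velocity")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        area_angle = ellipse_area(angle, coverage)
        area_vel = ellipse_area(vel, coverage)
    combined = rms(
        np.concatenate(
            [
                _normalized_magnitude(angle.pitch, angle.roll),
                _normalized_magnitude(vel.pitch, vel.roll),
            ]
        )
    )
    values = np.array(
        [
            rms(angle.pitch),
            rms(angle.roll),
            resultant_rms(angle.pitch, angle.roll),
            rms(vel.pitch),
            rms(vel.roll),
            resultant_rms(vel.pitch, vel.roll),
            path_length(angle),
            path_length(vel),
            area_angle,
            area_vel,
            combined,
        ]
    )
    return FeatureVector(values=values)
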