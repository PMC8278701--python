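"""Model-ready representations: standardized time series and 60x60 trajectory images.

Three inputs feed the classifiers: the hand-engineered feature vector
(:mod:`swaybalance.kinematics`), a multichannel time series, and a binary
pitch-vs-roll trajectory image.  All fitted state (channel statistics,
raster bounds) derives from training data only and is carried alongside any
trained model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .data_model import SwayRecording
from .kinematics import SwayTrajectory, integrate_angle

__all__ = [
    "IMAGE_SIDE",
    "ROTATION_ANGLE_SET",
    "ChannelConfig",
    "TimeSeriesInput",
    "RasterBounds",
    "ImageInput",
    "ChannelStats",
    "fit_channel_stats",
    "to_timeseries",
    "fit_bounds",
    "rasterize",
    "make_image_input",
    "augment_rotations",
    "rotate_trajectory",
]

#: side length, in pixels, of the square trajectory image
IMAGE_SIDE = 60

#: augmentation rotation angles, degrees
ROTATION_ANGLE_SET: tuple[float, ...] = (30.0, 60.0, 120.0, 150.0, 210.0, 240.0, 300.0, 330.0)


@dataclass(frozen=True)
class ChannelConfig:
    """Which channels enter the time-series representation and how they group.

    ``mode='angle_velocity'`` (default) yields 4 channels in 2 groups
    (integrated angles, raw velocities), matching the position-vs-velocity
    depth-wise convolution rationale.  ``mode='velocity_only'`` yields the
    literal 2-channel (pitch, roll velocity) reading.
    """

    mode: str = "angle_velocity"

    def __post_init__(self) -> None:
        if self.mode not in ("angle_velocity", "velocity_only"):
            raise ValueError(f"unknown channel mode {self.mode!r}")

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.mode == "velocity_only":
            return ("pitch_velocity", "roll_velocity")
        return ("pitch_angle", "roll_angle", "pitch_velocity", "roll_velocity")

    @property
    def groups(self) -> tuple[tuple[int, ...], ...]:
        """Partition of channel indices into input-type groups."""
        if self.mode == "velocity_only":
            return ((0, 1),)
        return ((0, 1), (2, 3))


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean/SD fitted on training data for standardization."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)
        if m.shape != s.shape or m.ndim != 1:
            raise ValueError("mean and sd must be equal-length 1-D arrays")
        if (s <= 0).any():
            raise ValueError("channel SDs must be positive")


@dataclass(frozen=True)
class TimeSeriesInput:
    """Standardized multichannel series for one repetition: (C, T) array."""

    channels: np.ndarray
    channel_names: tuple[str, ...]
    groups: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.channels, dtype=float)
        object.__setattr__(self, "channels", x)
        if x.ndim != 2:
            raise ValueError("channels must be a (C, T) array")
        if x.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel names")
        flat = sorted(i for g in self.groups for i in g)
        if flat != list(range(x.shape[0])):
            raise ValueError("groups must partition the channel indices exactly once")


@dataclass(frozen=True)
class RasterBounds:
    """Symmetric per-axis half-widths of the raster window, fitted on training data."""

    pitch_halfwidth: float
    roll_halfwidth: float

    def __post_init__(self) -> None:
        if not (self.pitch_halfwidth > 0 and self.roll_halfwidth > 0):
            raise ValueError("half-widths must be positive")


@dataclass(frozen=True)
class ImageInput:
    """Binary trajectory images for one repetition: (2, 60, 60), channels (angle, velocity)."""

    pixels: np.ndarray
    bounds: tuple[RasterBounds, RasterBounds]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        object.__setattr__(self, "pixels", px)
        if px.shape != (2, IMAGE_SIDE, IMAGE_SIDE):
            raise ValueError(f"expected (2, {IMAGE_SIDE}, {IMAGE_SIDE}) pixels, got {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("pixels must be binary")


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def _raw_channels(rec: SwayRecording, config: ChannelConfig) -> np.ndarray:
    if config.mode == "velocity_only":
        return np.stack([rec.pitch_velocity, rec.roll_velocity])
    angle = integrate_angle(rec)
    return np.stack([angle.pitch, angle.roll, rec.pitch_velocity, rec.roll_velocity])


def _fix_length(x: np.ndarray, target_len: int) -> np.ndarray:
    """Symmetric zero-padding / truncation of a (C, T) array to ``target_len``."""
    t = x.shape[1]
    if t == target_len:
        return x
    if t > target_len:
        start = (t - target_len) // 2
        return x[:, start : start + target_len]
    pad = target_len - t
    left = pad // 2
    return np.pad(x, ((0, 0), (left, pad - left)))


def fit_channel_stats(
    train: Iterable[SwayRecording], config: ChannelConfig | None = None
) -> ChannelStats:
    """Fit per-channel standardization statistics on the training recordings."""
    config = config or ChannelConfig()
    rows = [_raw_channels(rec, config) for rec in train]
    if not rows:
        raise ValueError("cannot fit channel statistics on an empty training set")
    stacked = np.concatenate(rows, axis=1)
    sd = stacked.std(axis=1)
    sd = np.where(sd > 0, sd, 1.0)
    return ChannelStats(mean=stacked.mean(axis=1), sd=sd)


def to_timeseries(
    rec: SwayRecording,
    config: ChannelConfig | None = None,
    stats: ChannelStats | None = None,
    target_len: int | None = None,
) -> TimeSeriesInput:
    """Build the standardized time-series input for one repetition.

    ``stats`` must come from :func:`fit_channel_stats` on training data;
    when omitted the channels are passed through unstandardized.
    """
    config = config or ChannelConfig()
    if rec.n_samples < 2:
        raise ValueError("recording too short for a time-series representation")
    x = _raw_channels(rec, config)
    if stats is not None:
        if stats.mean.size != x.shape[0]:
            raise ValueError("channel statistics do not match the channel config")
        x = (x - stats.mean[:, None]) / stats.sd[:, None]
    if target_len is None:
        target_len = rec.expected_samples
    x = _fix_length(x, target_len)
    return TimeSeriesInput(channels=x, channel_names=config.channel_names, groups=config.groups)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def fit_bounds(
    train: Sequence[SwayTrajectory],
    policy: str = "max_abs",
    percentile: float = 99.0,
) -> RasterBounds:
    """Fit the raster window half-widths on training trajectories.

    ``policy='max_abs'`` uses the maximum absolute excursion per axis;
    ``policy='percentile'`` uses the given percentile of absolute excursions
    pooled across all training samples.  Half-widths are floored at a tiny
    epsilon so a degenerate (all-zero) training set still rasterizes.
    """
    if len(train) == 0:
        raise ValueError("cannot fit raster bounds on an empty training set")
    pitch = np.concatenate([np.abs(t.pitch) for t in train])
    roll = np.concatenate([np.abs(t.roll) for t in train])
    if policy == "max_abs":
        hw_p, hw_r = float(pitch.max()), float(roll.max())
    elif policy == "percentile":
        hw_p = float(np.percentile(pitch, percentile))
        hw_r = float(np.percentile(roll, percentile))
    else:
        raise ValueError(f"unknown bounds policy {policy!r}")
    eps = 1e-9
    return RasterBounds(pitch_halfwidth=max(hw_p, eps), roll_halfwidth=max(hw_r, eps))


def _to_pixel(traj: SwayTrajectory, bounds: RasterBounds) -> tuple[np.ndarray, np.ndarray]:
    """Map (pitch, roll) samples to integer (col, row); out-of-bounds clamps to border."""
    u = (traj.pitch + bounds.pitch_halfwidth) / (2.0 * bounds.pitch_halfwidth)
    v = (bounds.roll_halfwidth - traj.roll) / (2.0 * bounds.roll_halfwidth)  # row 0 at +roll
    col = np.clip(np.floor(u * IMAGE_SIDE).astype(int), 0, IMAGE_SIDE - 1)
    row = np.clip(np.floor(v * IMAGE_SIDE).astype(int), 0, IMAGE_SIDE - 1)
    return col, row


def _bresenham(c0: int, r0: int, c1: int, r1: int) -> list[tuple[int, int]]:
    """Integer line rasterization between two pixels, inclusive."""
    points = []
    dc, dr = abs(c1 - c0), -abs(r1 - r0)
    sc = 1 if c0 < c1 else -1
    sr = 1 if r0 < r1 else -1
    err = dc + dr
    c, r = c0, r0
    while True:
        points.append((c, r))
        if c == c1 and r == r1:
            break
        e2 = 2 * err
        if e2 >= dr:
            err += dr
            c += sc
        if e2 <= dc:
            err += dc
            r += sr
    return points


def rasterize(
    traj: SwayTrajectory, bounds: RasterBounds, connect: bool = True
) -> np.ndarray:
    """Rasterize a 2-D trajectory onto a 60x60 binary grid.

    Pitch maps to columns, roll to rows (row 0 at +roll).  With
    ``connect=True`` (default) consecutive samples are joined by Bresenham
    line segments so the image depicts the drawn trajectory; with
    ``connect=False`` only the sample points themselves are lit.
    """
    if len(traj) == 0:
        raise ValueError("cannot rasterize an empty trajectory")
    grid = np.zeros((IMAGE_SIDE, IMAGE_SIDE), dtype=np.uint8)
    col, row = _to_pixel(traj, bounds)
    grid[row[0], col[0]] = 1
    if connect:
        for i in range(1, len(col)):
            a = (int(col[i - 1]), int(row[i - 1]))
            b = (int(col[i]), int(row[i]))
            if a > b:  # canonical direction: Bresenham is not endpoint-symmetric
                a, b = b, a
            for c, r in _bresenham(a[0], a[1], b[0], b[1]):
                grid[r, c] = 1
    else:
        grid[row, col] = 1
    return grid


def make_image_input(
    rec: SwayRecording,
    angle_bounds: RasterBounds,
    velocity_bounds: RasterBounds,
    connect: bool = True,
) -> ImageInput:
    """Rasterize the angle and velocity trajectories into the two image channels."""
    angle = integrate_angle(rec)
    vel = SwayTrajectory(pitch=rec.pitch_velocity, roll=rec.roll_velocity, kind="velocity")
    px = np.stack(
        [rasterize(angle, angle_bounds, connect), rasterize(vel, velocity_bounds, connect)]
    )
    return ImageInput(pixels=px, bounds=(angle_bounds, velocity_bounds))


def rotate_trajectory(traj: SwayTrajectory, angle_deg: float) -> SwayTrajectory:
    """Rotate the (pitch, roll) samples by ``angle_deg`` about the origin."""
    theta = np.deg2rad(angle_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    return SwayTrajectory(
        pitch=cos * traj.pitch - sin * traj.roll,
        roll=sin * traj.pitch + cos * traj.roll,
        kind=traj.kind,
    )


def augment_rotations(
    rec: SwayRecording,
    angle_bounds: RasterBounds,
    velocity_bounds: RasterBounds,
    n_copies: int = 3,
    angle_set: Sequence[float] = ROTATION_ANGLE_SET,
    seed: int = 0,
    connect: bool = True,
) -> list[ImageInput]:
    """Rotation augmentation for a training-set recording.

    Draws ``n_copies`` angles uniformly (with replacement) from
    ``angle_set`` and rotates the underlying coordinates before
    rasterization — exact and free of pixel-interpolation artifacts.
    """
    if len(angle_set) == 0:
        raise ValueError("angle_set must not be empty")
    rng = np.random.Generator(np.random.PCG64(seed))
    angles = rng.choice(np.asarray(angle_set, dtype=float), size=n_copies, replace=True)
    angle = integrate_angle(rec)
    vel = SwayTrajectory(pitch=rec.pitch_velocity, roll=rec.roll_velocity, kind="velocity")
    out = []
    for a in angles:
        px = np.stack(
            [
                rasterize(rotate_trajectory(angle, a), angle_bounds, connect),
                rasterize(rotate_trajectory(vel, a), velocity_bounds, connect),
            ]
        )
        out.append(ImageInput(pixels=px, bounds=(angle_bounds, velocity_bounds)))
    return out
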