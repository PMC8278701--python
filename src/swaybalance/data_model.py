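"""Domain types, on-disk formats, validity filtering, and participant-wise splits.

On-disk layout
--------------
A dataset directory contains:

* ``manifest.csv`` — one row per exercise repetition with columns
  ``repetition_id, participant_id, exercise_id, signal_path,
  pt_rating_1 .. pt_rating_8, self_rating, step_out_count`` (rating cells are
  blank when the corresponding rater did not rate the repetition).
* per-repetition signal CSVs (columns ``time_s, pitch_velocity_dps,
  roll_velocity_dps``) referenced by ``signal_path`` relative to the manifest.
* ``exercise_metadata.yaml`` (optional) — per-exercise condition descriptors.

Angles are in degrees and angular velocities in deg/s throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SwayRecording",
    "RatingSet",
    "Dataset",
    "DatasetSplit",
    "ExclusionReport",
    "FormatError",
    "ConfigurationError",
    "MAX_RATERS",
    "load_recording",
    "write_recording",
    "load_dataset",
    "save_dataset",
    "filter_valid",
    "split_by_participant",
]

#: maximum size of the physical-therapist rating panel
MAX_RATERS = 8

#: relative tolerance on time-step uniformity when inferring the sample rate
_DT_RTOL = 1e-3

SURFACES = ("firm", "foam")
STANCES = ("feet_apart", "feet_together", "partial_heel_toe", "heel_toe", "single_leg")
VISIONS = ("open", "closed")
HEADS = ("none", "pitch", "yaw")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the documented format."""


class ConfigurationError(ValueError):
    """Raised when caller-supplied configuration is incomplete or inconsistent."""


@dataclass(frozen=True)
class SwayRecording:
    """One repetition's two-channel angular-velocity series.

    Parameters
    ----------
    repetition_id, participant_id, exercise_id
        Identifiers linking the signal to the manifest.
    sample_rate
        Samples per second (nominally 100).
    pitch_velocity, roll_velocity
        Angular velocity in deg/s; equal-length 1-D arrays.
    duration
        Nominal repetition duration in seconds (nominally 30).
    """

    repetition_id: str
    participant_id: str
    exercise_id: str
    sample_rate: float
    pitch_velocity: np.ndarray
    roll_velocity: np.ndarray
    duration: float = 30.0

    def __post_init__(self) -> None:
        pv = np.asarray(self.pitch_velocity, dtype=float)
        rv = np.asarray(self.roll_velocity, dtype=float)
        object.__setattr__(self, "pitch_velocity", pv)
        object.__setattr__(self, "roll_velocity", rv)
        if pv.ndim != 1 or rv.ndim != 1:
            raise FormatError("velocity channels must be 1-D")
        if pv.size != rv.size:
            raise FormatError(
                f"channel length mismatch: pitch {pv.size} vs roll {rv.size}"
            )
        if pv.size < 1:
            raise FormatError("recording must contain at least one sample")
        if not (self.sample_rate > 0):
            raise FormatError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.isfinite(pv).all() or not np.isfinite(rv).all():
            bad = int(np.flatnonzero(~(np.isfinite(pv) & np.isfinite(rv)))[0])
            raise FormatError(f"non-finite sample at index {bad}")

    @property
    def n_samples(self) -> int:
        return int(self.pitch_velocity.size)

    @property
    def expected_samples(self) -> int:
        """Sample count implied by the nominal duration."""
        return int(round(self.duration * self.sample_rate))

    def is_complete(self, tolerance_samples: int = 1) -> bool:
        """True when the recording is within ``tolerance_samples`` of its nominal length."""
        return self.n_samples >= self.expected_samples - tolerance_samples


@dataclass(frozen=True)
class RatingSet:
    """The PT panel's ratings plus the participant's self-assessment.

    ``pt_ratings`` maps rater ID -> rating in {1..5}; ``self_rating`` is in
    {1..5} or ``None`` when the participant did not self-assess.
    """

    pt_ratings: Mapping[str, int]
    self_rating: int | None = None

    def __post_init__(self) -> None:
        ratings = dict(self.pt_ratings)
        object.__setattr__(self, "pt_ratings", ratings)
        for rater, r in ratings.items():
            if r not in (1, 2, 3, 4, 5):
                raise FormatError(f"rating {r!r} from rater {rater!r} not in 1..5")
        if self.self_rating is not None and self.self_rating not in (1, 2, 3, 4, 5):
            raise FormatError(f"self rating {self.self_rating!r} not in 1..5")

    @property
    def n_raters(self) -> int:
        return len(self.pt_ratings)

    @property
    def values(self) -> tuple[int, ...]:
        """Panel ratings ordered by rater ID (stable across runs)."""
        return tuple(self.pt_ratings[k] for k in sorted(self.pt_ratings))


@dataclass
class Dataset:
    """A collection of recordings with their rating sets and metadata."""

    recordings: dict[str, SwayRecording] = field(default_factory=dict)
    ratings: dict[str, RatingSet] = field(default_factory=dict)
    step_outs: dict[str, int] = field(default_factory=dict)
    exercise_metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.ratings) - set(self.recordings)
        if missing:
            raise FormatError(
                f"rated repetitions without recordings: {sorted(missing)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def repetition_ids(self) -> list[str]:
        return sorted(self.recordings)

    @property
    def participant_ids(self) -> list[str]:
        return sorted({r.participant_id for r in self.recordings.values()})

    def subset(self, repetition_ids: Iterable[str]) -> "Dataset":
        keep = set(repetition_ids)
        return Dataset(
            recordings={k: v for k, v in self.recordings.items() if k in keep},
            ratings={k: v for k, v in self.ratings.items() if k in keep},
            step_outs={k: v for k, v in self.step_outs.items() if k in keep},
            exercise_metadata=dict(self.exercise_metadata),
        )


@dataclass
class DatasetSplit:
    """Participant-disjoint train/validation/test partition."""

    train: Dataset
    validation: Dataset
    test: Dataset

    def __post_init__(self) -> None:
        parts = {
            "train": set(self.train.participant_ids),
            "validation": set(self.validation.participant_ids),
            "test": set(self.test.participant_ids),
        }
        names = list(parts)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                overlap = parts[a] & parts[b]
                if overlap:
                    raise ConfigurationError(
                        f"participants {sorted(overlap)} appear in both {a} and {b}"
                    )


@dataclass(frozen=True)
class ExclusionReport:
    """Counts of repetitions dropped by :func:`filter_valid`, per reason."""

    missing_label: int = 0
    premature: int = 0

    @property
    def total(self) -> int:
        return self.missing_label + self.premature


# ---------------------------------------------------------------------------
# signal file I/O
# ---------------------------------------------------------------------------

def write_recording(rec: SwayRecording, path: str | Path) -> None:
    """Write a recording as a delimited-text signal file."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sample_rate
    df = pd.DataFrame(
        {
            "time_s": t,
            "pitch_velocity_dps": rec.pitch_velocity,
            "roll_velocity_dps": rec.roll_velocity,
        }
    )
    df.to_csv(path, index=False)  # pandas writes shortest round-trip reprs


def load_recording(
    path: str | Path,
    repetition_id: str = "",
    participant_id: str = "",
    exercise_id: str = "",
    duration: float | None = None,
    expected_sample_rate: float | None = None,
) -> SwayRecording:
    """Load a per-repetition signal CSV and validate it.

    The sample rate is inferred from the ``time_s`` column and, when
    ``expected_sample_rate`` is given (e.g. from the manifest), checked
    against it.

    Raises
    ------
    FormatError
        On missing columns, non-finite samples, or non-uniform time steps,
        naming the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 — re-raise as format error
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    required = ("time_s", "pitch_velocity_dps", "roll_velocity_dps")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 rows to infer sample rate")
    for col in required:
        vals = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise FormatError(f"{path}: non-finite {col} at row {int(bad[0])}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise FormatError(f"{path}: non-increasing time column")
    off = np.flatnonzero(np.abs(dt - med) > _DT_RTOL * med)
    if off.size:
        raise FormatError(
            f"{path}: non-uniform time step at row {int(off[0]) + 1} "
            f"(dt={dt[off[0]]:.6g}, expected {med:.6g})"
        )
    sample_rate = 1.0 / med
    if expected_sample_rate is not None and not math.isclose(
        sample_rate, expected_sample_rate, rel_tol=1e-3
    ):
        raise FormatError(
            f"{path}: inferred sample rate {sample_rate:.4g} Hz disagrees with "
            f"manifest value {expected_sample_rate:.4g} Hz"
        )
    n = len(df)
    if duration is None:
        duration = n / sample_rate
    return SwayRecording(
        repetition_id=repetition_id or path.stem,
        participant_id=participant_id,
        exercise_id=exercise_id,
        sample_rate=sample_rate,
        pitch_velocity=df["pitch_velocity_dps"].to_numpy(dtype=float),
        roll_velocity=df["roll_velocity_dps"].to_numpy(dtype=float),
        duration=duration,
    )


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------

def _rating_columns() -> list[str]:
    return [f"pt_rating_{i}" for i in range(1, MAX_RATERS + 1)]


def save_dataset(ds: Dataset, out_dir: str | Path, signal_subdir: str = "signals") -> Path:
    """Write manifest, signal CSVs and exercise metadata; returns the manifest path."""
    out_dir = Path(out_dir)
    sig_dir = out_dir / signal_subdir
    sig_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rid in ds.repetition_ids:
        rec = ds.recordings[rid]
        rel = f"{signal_subdir}/{rid}.csv"
        write_recording(rec, out_dir / rel)
        row: dict[str, object] = {
            "repetition_id": rid,
            "participant_id": rec.participant_id,
            "exercise_id": rec.exercise_id,
            "signal_path": rel,
        }
        rs = ds.ratings.get(rid)
        for col in _rating_columns():
            row[col] = ""
        if rs is not None:
            for rater, rating in rs.pt_ratings.items():
                row[f"pt_rating_{int(rater)}"] = rating
            row["self_rating"] = "" if rs.self_rating is None else rs.self_rating
        else:
            row["self_rating"] = ""
        row["step_out_count"] = ds.step_outs.get(rid, "")
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    cols = (
        ["repetition_id", "participant_id", "exercise_id", "signal_path"]
        + _rating_columns()
        + ["self_rating", "step_out_count"]
    )
    pd.DataFrame(rows, columns=cols).to_csv(manifest, index=False)
    if ds.exercise_metadata:
        with open(out_dir / "exercise_metadata.yaml", "w") as fh:
            yaml.safe_dump(ds.exercise_metadata, fh, sort_keys=True)
    return manifest


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Load a dataset from its manifest CSV (signal paths resolved relative to it)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    recordings: dict[str, SwayRecording] = {}
    ratings: dict[str, RatingSet] = {}
    step_outs: dict[str, int] = {}
    for i, row in df.iterrows():
        rid = row["repetition_id"]
        rec = load_recording(
            base / row["signal_path"],
            repetition_id=rid,
            participant_id=row["participant_id"],
            exercise_id=row["exercise_id"],
        )
        recordings[rid] = rec
        pt: dict[str, int] = {}
        for j in range(1, MAX_RATERS + 1):
            cell = row.get(f"pt_rating_{j}", "")
            if cell != "":
                pt[str(j)] = int(float(cell))
        self_cell = row.get("self_rating", "")
        self_rating = int(float(self_cell)) if self_cell != "" else None
        if pt or self_rating is not None:
            ratings[rid] = RatingSet(pt_ratings=pt, self_rating=self_rating)
        so = row.get("step_out_count", "")
        if so != "":
            step_outs[rid] = int(float(so))
    meta_path = base / "exercise_metadata.yaml"
    metadata: dict[str, dict] = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            metadata = yaml.safe_load(fh) or {}
    return Dataset(
        recordings=recordings,
        ratings=ratings,
        step_outs=step_outs,
        exercise_metadata=metadata,
    )


# ---------------------------------------------------------------------------
# filtering and splitting
# ---------------------------------------------------------------------------

def filter_valid(
    ds: Dataset, min_duration: float | None = None
) -> tuple[Dataset, ExclusionReport]:
    """Drop unlabeled and prematurely-terminated repetitions.

    A repetition is *unlabeled* when it has no PT ratings at all (a
    self-assessment alone does not count).  It is *premature* when its sample
    count falls short of ``min_duration`` (default: the recording's nominal
    duration) by more than one sample period.
    """
    keep: list[str] = []
    missing = premature = 0
    for rid in ds.repetition_ids:
        rec = ds.recordings[rid]
        rs = ds.ratings.get(rid)
        if rs is None or rs.n_raters == 0:
            missing += 1
            continue
        threshold = (
            rec.expected_samples
            if min_duration is None
            else int(round(min_duration * rec.sample_rate))
        )
        if rec.n_samples < threshold - 1:
            premature += 1
            continue
        keep.append(rid)
    return ds.subset(keep), ExclusionReport(missing_label=missing, premature=premature)


def split_by_participant(
    ds: Dataset, assignment: Mapping[str, str]
) -> DatasetSplit:
    """Route every repetition by its participant's train/validation/test assignment."""
    valid_parts = {"train", "validation", "test"}
    unassigned = [p for p in ds.participant_ids if p not in assignment]
    if unassigned:
        raise ConfigurationError(f"participants without assignment: {unassigned}")
    bad = {p: a for p, a in assignment.items() if a not in valid_parts}
    if bad:
        raise ConfigurationError(f"invalid assignments (use train/validation/test): {bad}")
    buckets: dict[str, list[str]] = {p: [] for p in valid_parts}
    for rid in ds.repetition_ids:
        buckets[assignment[ds.recordings[rid].participant_id]].append(rid)
    return DatasetSplit(
        train=ds.subset(buckets["train"]),
        validation=ds.subset(buckets["validation"]),
        test=ds.subset(buckets["test"]),
    )


def default_assignment(participant_ids: Iterable[str]) -> dict[str, str]:
    """Study-style split: first 6 participants train, next 2 validation, last 2 test.

    Participants are ordered by any trailing integer in their ID (then
    lexicographically), so ``P01 .. P10`` splits as 1-6 / 7-8 / 9-10.
    """
    def key(pid: str):
        digits = "".join(ch for ch in pid if ch.isdigit())
        return (int(digits) if digits else 0, pid)

    ordered = sorted(participant_ids, key=key)
    n = len(ordered)
    if n < 3:
        raise ConfigurationError("need at least 3 participants for a 3-way split")
    n_train = max(1, int(round(n * 0.6)))
    n_val = max(1, int(round(n * 0.2)))
    if n_train + n_val >= n:
        n_train, n_val = n - 2, 1
    out = {}
    for i, pid in enumerate(ordered):
        if i < n_train:
            out[pid] = "train"
        elif i < n_train + n_val:
            out[pid] = "validation"
        else:
            out[pid] = "test"
    return out
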