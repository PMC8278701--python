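"""Synthetic posturography datasets with a severity-graded generative model.

The generator produces the statistical structure the downstream method
assumes, without claiming biomechanical realism:

* band-limited Gaussian trunk sway whose resultant RMS grows linearly with a
  latent severity in [0, 1];
* pitch/roll anisotropy (pitch sways more than roll);
* occasional step-out transients (half-sine excursions) whose expected count
  grows with severity;
* a panel of 1-8 noisy ordinal raters thresholding the latent severity, plus
  a systematically optimistic self-assessment.

All randomness flows through :class:`numpy.random.SeedSequence` with a
counter-based spawn scheme, so any repetition can be regenerated in
isolation and identical seeds give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .data_model import Dataset, MAX_RATERS, RatingSet, SwayRecording

__all__ = [
    "SimulationConfig",
    "LatentSeverity",
    "simulate_repetition",
    "simulate_raters",
    "simulate_dataset",
    "severity_to_rating",
]

# stream tags for the counter-based sub-seed scheme
_STREAM_SIGNAL = 0
_STREAM_RATERS = 1
_STREAM_STRUCTURE = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults mirror the study's scale."""

    n_participants: int = 10
    n_exercises_per_participant: int = 15
    n_repetitions: int = 3
    duration: float = 30.0
    sample_rate: float = 100.0
    sway_band: tuple[float, float] = (0.1, 3.0)
    base_rms: float = 0.5          # deg/s resultant RMS at severity 0
    rms_gain: float = 6.0          # deg/s per unit severity
    anisotropy: float = 1.4        # pitch:roll RMS ratio
    stepout_rate: float = 2.0      # expected step-outs per repetition at severity 1
    n_raters_mean: float = 4.28
    rater_noise_sd: float = 0.12   # severity units
    self_bias: float = 0.15        # severity units subtracted before self rating
    rating_thresholds: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    severity_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        th = tuple(self.rating_thresholds)
        if len(th) != 4 or any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("rating_thresholds must be 4 strictly increasing values")
        if not (0 < th[0] and th[-1] < 1):
            raise ValueError("rating_thresholds must lie in (0, 1)")
        for name in ("base_rms", "rms_gain", "anisotropy", "sample_rate", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stepout_rate < 0 or self.rater_noise_sd < 0:
            raise ValueError("rates and noise levels must be non-negative")
        lo, hi = self.sway_band
        if not (0 <= lo < hi <= self.sample_rate / 2):
            raise ValueError("sway_band must satisfy 0 <= lo < hi <= Nyquist")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "sway_band" in d:
            d["sway_band"] = tuple(d["sway_band"])
        if "rating_thresholds" in d:
            d["rating_thresholds"] = tuple(d["rating_thresholds"])
        return cls(**d)


@dataclass(frozen=True)
class LatentSeverity:
    """Latent decomposition of one repetition's difficulty."""

    participant_ability: float
    exercise_difficulty: float
    repetition_severity: float

    def __post_init__(self) -> None:
        for v in (self.participant_ability, self.exercise_difficulty, self.repetition_severity):
            if not (0.0 <= v <= 1.0):
                raise ValueError("latent severities must lie in [0, 1]")


def _sub_rng(master_seed: int, *path: int) -> np.random.Generator:
    """Counter-based sub-stream: a fresh generator for (master_seed, *path)."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((master_seed, *path))))


def severity_to_rating(value: float, thresholds: Sequence[float]) -> int:
    """Ordinal bin of a (possibly noisy) severity value against the cut points."""
    return 1 + int(np.searchsorted(np.asarray(thresholds), value, side="right"))


def _band_limited_noise(rng: np.random.Generator, n: int, sample_rate: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise with spectrum confined to ``band`` (Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("sway band contains no FFT bins at this length/rate")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        return x
    return x / rms


def simulate_repetition(
    severity: float, cfg: SimulationConfig, seed: int
) -> tuple[SwayRecording, int]:
    """Generate one repetition's sway signal at the given latent severity.

    Returns the recording and the number of injected step-out transients.
    The stationary part has exact empirical resultant RMS
    ``base_rms + rms_gain * severity`` split across pitch/roll so that
    pitch RMS = anisotropy x roll RMS.  Deterministic given
    ``(severity, cfg, seed)``.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    rng = _sub_rng(seed, _STREAM_SIGNAL)
    n = int(round(cfg.duration * cfg.sample_rate))
    target = cfg.base_rms + cfg.rms_gain * severity
    # resultant RMS^2 = pitch RMS^2 + roll RMS^2 with pitch = anisotropy * roll
    roll_rms = target / np.sqrt(1.0 + cfg.anisotropy**2)
    pitch_rms = cfg.anisotropy * roll_rms
    pitch = pitch_rms * _band_limited_noise(rng, n, cfg.sample_rate, cfg.sway_band)
    roll = roll_rms * _band_limited_noise(rng, n, cfg.sample_rate, cfg.sway_band)

    n_stepouts = int(rng.poisson(cfg.stepout_rate * severity))
    for _ in range(n_stepouts):
        dur_s = rng.uniform(0.5, 1.5)
        width = max(2, int(round(dur_s * cfg.sample_rate)))
        start = int(rng.integers(0, max(1, n - width)))
        amp = rng.uniform(3.0, 5.0) * target
        theta = rng.uniform(0.0, 2.0 * np.pi)  # direction of the excursion
        pulse = amp * np.sin(np.pi * np.arange(width) / (width - 1))
        stop = min(n, start + width)
        pitch[start:stop] += np.cos(theta) * pulse[: stop - start]
        roll[start:stop] += np.sin(theta) * pulse[: stop - start]

    rec = SwayRecording(
        repetition_id="",
        participant_id="",
        exercise_id="",
        sample_rate=cfg.sample_rate,
        pitch_velocity=pitch,
        roll_velocity=roll,
        duration=cfg.duration,
    )
    return rec, n_stepouts


def simulate_raters(severity: float, cfg: SimulationConfig, seed: int) -> RatingSet:
    """Simulate the PT panel and the self-assessment for one repetition.

    Panel size is drawn from {1..8} with mean approximately
    ``cfg.n_raters_mean``; each rating is the ordinal bin of
    ``severity + N(0, rater_noise_sd)``.  The self rating subtracts
    ``self_bias`` first, yielding systematic underestimation.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValueError(f"severity must lie in [0, 1], got {severity}")
    rng = _sub_rng(seed, _STREAM_RATERS)
    p = min(1.0, cfg.n_raters_mean / MAX_RATERS)
    n_raters = int(rng.binomial(MAX_RATERS, p))
    n_raters = max(1, n_raters)
    panel = rng.choice(np.arange(1, MAX_RATERS + 1), size=n_raters, replace=False)
    pt: dict[str, int] = {}
    for rater in sorted(int(r) for r in panel):
        noisy = severity + rng.normal(0.0, cfg.rater_noise_sd) if cfg.rater_noise_sd > 0 else severity
        pt[str(rater)] = severity_to_rating(noisy, cfg.rating_thresholds)
    self_val = severity - cfg.self_bias
    if cfg.rater_noise_sd > 0:
        self_val += rng.normal(0.0, cfg.rater_noise_sd)
    self_rating = severity_to_rating(self_val, cfg.rating_thresholds)
    return RatingSet(pt_ratings=pt, self_rating=self_rating)


def draw_latents(cfg: SimulationConfig) -> dict[str, LatentSeverity]:
    """Draw per-repetition latent severities for the whole design grid."""
    rng = _sub_rng(cfg.seed, _STREAM_STRUCTURE)
    abilities = rng.uniform(0.0, 1.0, size=cfg.n_participants)
    out: dict[str, LatentSeverity] = {}
    for p in range(cfg.n_participants):
        difficulties = rng.uniform(0.0, 1.0, size=cfg.n_exercises_per_participant)
        for e in range(cfg.n_exercises_per_participant):
            for r in range(cfg.n_repetitions):
                jitter = rng.normal(0.0, cfg.severity_jitter_sd)
                sev = float(np.clip(abilities[p] + difficulties[e] - 0.5 + jitter, 0.0, 1.0))
                rid = f"P{p + 1:02d}_E{e + 1:02d}_R{r + 1}"
                out[rid] = LatentSeverity(
                    participant_ability=float(abilities[p]),
                    exercise_difficulty=float(difficulties[e]),
                    repetition_severity=sev,
                )
    return out


_EXERCISE_GRID = [
    {"surface": s, "stance": st, "vision": v, "head": h}
    for s in ("firm", "foam")
    for st in ("feet_apart", "feet_together", "partial_heel_toe", "heel_toe", "single_leg")
    for v in ("open", "closed")
    for h in ("none", "pitch", "yaw")
]


def simulate_dataset(cfg: SimulationConfig) -> Dataset:
    """Generate a full labeled dataset from the configured design grid.

    The repetition count is
    ``n_participants * n_exercises_per_participant * n_repetitions``
    (450 at the default configuration).
    """
    latents = draw_latents(cfg)
    recordings: dict[str, SwayRecording] = {}
    ratings: dict[str, RatingSet] = {}
    step_outs: dict[str, int] = {}
    meta_rng = _sub_rng(cfg.seed, _STREAM_STRUCTURE, 1)
    exercise_metadata: dict[str, dict] = {}
    for p in range(cfg.n_participants):
        for e in range(cfg.n_exercises_per_participant):
            eid = f"P{p + 1:02d}_EX{e + 1:02d}"
            exercise_metadata[eid] = dict(
                _EXERCISE_GRID[int(meta_rng.integers(0, len(_EXERCISE_GRID)))]
            )
            for r in range(cfg.n_repetitions):
                rid = f"P{p + 1:02d}_E{e + 1:02d}_R{r + 1}"
                sev = latents[rid].repetition_severity
                # counter-based sub-seed: (master, participant, exercise, rep)
                sub_seed = np.random.SeedSequence((cfg.seed, p, e, r)).generate_state(1)[0]
                rec, n_so = simulate_repetition(sev, cfg, int(sub_seed))
                rec = SwayRecording(
                    repetition_id=rid,
                    participant_id=f"P{p + 1:02d}",
                    exercise_id=eid,
                    sample_rate=rec.sample_rate,
                    pitch_velocity=rec.pitch_velocity,
                    roll_velocity=rec.roll_velocity,
                    duration=rec.duration,
                )
                recordings[rid] = rec
                ratings[rid] = simulate_raters(sev, cfg, int(sub_seed))
                step_outs[rid] = n_so
    return Dataset(
        recordings=recordings,
        ratings=ratings,
        step_outs=step_outs,
        exercise_metadata=exercise_metadata,
    )
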