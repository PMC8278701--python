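import numpy as np
import pytest

from swaybalance.data_model import Dataset, RatingSet, SwayRecording
from swaybalance.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """A fast simulation configuration for unit tests (short, low-rate signals)."""
    return SimulationConfig(
        n_participants=3,
        n_exercises_per_participant=2,
        n_repetitions=1,
        duration=2.0,
        sample_rate=50.0,
        seed=42,
    )


def make_recording(
    pitch,
    roll,
    sample_rate=100.0,
    repetition_id="rep",
    participant_id="P01",
    exercise_id="E01",
    duration=None,
):
    pitch = np.asarray(pitch, dtype=float)
    if duration is None:
        duration = pitch.size / sample_rate
    return SwayRecording(
        repetition_id=repetition_id,
        participant_id=participant_id,
        exercise_id=exercise_id,
        sample_rate=sample_rate,
        pitch_velocity=pitch,
        roll_velocity=np.asarray(roll, dtype=float),
        duration=duration,
    )


def make_dataset(n_reps=6, n_per_participant=2, sample_rate=50.0, duration=1.0, seed=0):
    """A small labeled dataset with deterministic random signals."""
    gen = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    recordings, ratings = {}, {}
    for i in range(n_reps):
        rid = f"r{i:02d}"
        pid = f"P{i // n_per_participant + 1:02d}"
        recordings[rid] = make_recording(
            gen.standard_normal(n),
            gen.standard_normal(n),
            sample_rate=sample_rate,
            repetition_id=rid,
            participant_id=pid,
            duration=duration,
        )
        ratings[rid] = RatingSet(
            pt_ratings={"1": int(gen.integers(1, 6)), "2": int(gen.integers(1, 6))},
            self_rating=int(gen.integers(1, 6)),
        )
    return Dataset(recordings=recordings, ratings=ratings)
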