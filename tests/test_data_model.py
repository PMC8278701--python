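import numpy as np
import pandas as pd
import pytest

from swaybalance.data_model import (
    ConfigurationError,
    Dataset,
    FormatError,
    RatingSet,
    SwayRecording,
    default_assignment,
    filter_valid,
    load_dataset,
    load_recording,
    save_dataset,
    split_by_participant,
    write_recording,
)

from conftest import make_dataset, make_recording


class TestSwayRecording:
    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError, match="mismatch"):
            make_recording([1.0, 2.0], [1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(FormatError, match="non-finite"):
            make_recording([1.0, np.nan], [1.0, 2.0])

    def test_bad_sample_rate_rejected(self):
        with pytest.raises(FormatError):
            make_recording([1.0], [1.0], sample_rate=0.0, duration=1.0)

    def test_completeness(self):
        rec = make_recording(np.zeros(100), np.zeros(100), sample_rate=100.0, duration=1.0)
        assert rec.is_complete()
        short = make_recording(np.zeros(90), np.zeros(90), sample_rate=100.0, duration=1.0)
        assert not short.is_complete()


class TestRatingSet:
    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            RatingSet(pt_ratings={"1": 6})

    def test_values_ordered_by_rater(self):
        rs = RatingSet(pt_ratings={"3": 5, "1": 2})
        assert rs.values == (2, 5)


class TestSignalIO:
    def test_load_3000_rows_at_100hz(self, tmp_path):
        path = tmp_path / "sig.csv"
        t = np.arange(3000) * 0.01
        pd.DataFrame(
            {"time_s": t, "pitch_velocity_dps": np.sin(t), "roll_velocity_dps": np.cos(t)}
        ).to_csv(path, index=False)
        rec = load_recording(path)
        assert rec.n_samples == 3000
        assert rec.sample_rate == pytest.approx(100.0, rel=1e-6)

    def test_nan_sample_is_format_error(self, tmp_path):
        path = tmp_path / "sig.csv"
        pd.DataFrame(
            {
                "time_s": [0.0, 0.01, 0.02],
                "pitch_velocity_dps": [0.0, np.nan, 0.0],
                "roll_velocity_dps": [0.0, 0.0, 0.0],
            }
        ).to_csv(path, index=False)
        with pytest.raises(FormatError, match="row 1"):
            load_recording(path)

    def test_non_uniform_time_step_names_row(self, tmp_path):
        path = tmp_path / "sig.csv"
        pd.DataFrame(
            {
                "time_s": [0.0, 0.01, 0.05, 0.06],
                "pitch_velocity_dps": np.zeros(4),
                "roll_velocity_dps": np.zeros(4),
            }
        ).to_csv(path, index=False)
        with pytest.raises(FormatError, match="non-uniform"):
            load_recording(path)

    def test_round_trip_full_precision(self, tmp_path, rng):
        rec = make_recording(rng.standard_normal(250), rng.standard_normal(250), sample_rate=50.0)
        write_recording(rec, tmp_path / "sig.csv")
        back = load_recording(tmp_path / "sig.csv")
        np.testing.assert_array_equal(back.pitch_velocity, rec.pitch_velocity)
        np.testing.assert_array_equal(back.roll_velocity, rec.roll_velocity)
        assert back.sample_rate == pytest.approx(rec.sample_rate, rel=1e-6)

    def test_manifest_sample_rate_mismatch(self, tmp_path, rng):
        rec = make_recording(rng.standard_normal(100), rng.standard_normal(100), sample_rate=50.0)
        write_recording(rec, tmp_path / "sig.csv")
        with pytest.raises(FormatError, match="disagrees"):
            load_recording(tmp_path / "sig.csv", expected_sample_rate=100.0)


class TestDatasetIO:
    def test_save_load_round_trip(self, tmp_path):
        ds = make_dataset(n_reps=4)
        manifest = save_dataset(ds, tmp_path)
        back = load_dataset(manifest)
        assert back.repetition_ids == ds.repetition_ids
        for rid in ds.repetition_ids:
            np.testing.assert_array_equal(
                back.recordings[rid].pitch_velocity, ds.recordings[rid].pitch_velocity
            )
            assert back.ratings[rid].pt_ratings == ds.ratings[rid].pt_ratings
            assert back.ratings[rid].self_rating == ds.ratings[rid].self_rating

    def test_load_save_load_idempotent(self, tmp_path):
        ds = make_dataset(n_reps=4)
        m1 = save_dataset(ds, tmp_path / "a")
        ds1 = load_dataset(m1)
        m2 = save_dataset(ds1, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_text() == (
            tmp_path / "b" / "manifest.csv"
        ).read_text()

    def test_rated_repetition_must_resolve(self):
        with pytest.raises(FormatError, match="without recordings"):
            Dataset(recordings={}, ratings={"ghost": RatingSet(pt_ratings={"1": 3})})


class TestFilterValid:
    def _mixed_dataset(self):
        ds = make_dataset(n_reps=10, duration=1.0, sample_rate=50.0)
        # one unlabeled, two short
        del ds.ratings["r00"]
        for rid in ("r01", "r02"):
            rec = ds.recordings[rid]
            ds.recordings[rid] = make_recording(
                rec.pitch_velocity[:20],
                rec.roll_velocity[:20],
                sample_rate=50.0,
                repetition_id=rid,
                participant_id=rec.participant_id,
                duration=1.0,
            )
        return ds

    def test_exclusion_counts(self):
        kept, report = filter_valid(self._mixed_dataset())
        assert len(kept) == 7
        assert report.missing_label == 1
        assert report.premature == 2

    def test_identity_when_all_valid(self):
        ds = make_dataset(n_reps=5)
        kept, report = filter_valid(ds)
        assert kept.repetition_ids == ds.repetition_ids
        assert report.total == 0

    def test_idempotent(self):
        kept1, _ = filter_valid(self._mixed_dataset())
        kept2, report2 = filter_valid(kept1)
        assert kept2.repetition_ids == kept1.repetition_ids
        assert report2.total == 0

    def test_study_scale_counts(self):
        """450 repetitions with 3 unlabeled and 4 truncated -> 443 retained."""
        ds = make_dataset(n_reps=450, n_per_participant=45, duration=0.2, sample_rate=50.0)
        for rid in list(ds.repetition_ids)[:3]:
            del ds.ratings[rid]
        for rid in list(ds.repetition_ids)[3:7]:
            rec = ds.recordings[rid]
            ds.recordings[rid] = make_recording(
                rec.pitch_velocity[:3],
                rec.roll_velocity[:3],
                sample_rate=50.0,
                repetition_id=rid,
                participant_id=rec.participant_id,
                duration=0.2,
            )
        kept, report = filter_valid(ds)
        assert len(kept) == 443
        assert report.missing_label == 3
        assert report.premature == 4


class TestSplit:
    def test_6_2_2_partition(self):
        ds = make_dataset(n_reps=30, n_per_participant=3)  # 10 participants
        pids = ds.participant_ids
        assignment = {p: "train" for p in pids[:6]}
        assignment.update({p: "validation" for p in pids[6:8]})
        assignment.update({p: "test" for p in pids[8:]})
        split = split_by_participant(ds, assignment)
        assert set(split.train.participant_ids) == set(pids[:6])
        assert set(split.validation.participant_ids) == set(pids[6:8])
        assert set(split.test.participant_ids) == set(pids[8:])
        assert len(split.train) + len(split.validation) + len(split.test) == len(ds)

    def test_all_train(self):
        ds = make_dataset(n_reps=6)
        split = split_by_participant(ds, {p: "train" for p in ds.participant_ids})
        assert len(split.validation) == 0 and len(split.test) == 0
        assert len(split.train) == len(ds)

    def test_unassigned_participant_rejected(self):
        ds = make_dataset(n_reps=6)
        with pytest.raises(ConfigurationError, match="without assignment"):
            split_by_participant(ds, {ds.participant_ids[0]: "train"})

    @pytest.mark.parametrize("seed", range(5))
    def test_no_participant_straddles_parts(self, seed):
        ds = make_dataset(n_reps=24, n_per_participant=4)
        gen = np.random.default_rng(seed)
        assignment = {
            p: ["train", "validation", "test"][gen.integers(0, 3)]
            for p in ds.participant_ids
        }
        split = split_by_participant(ds, assignment)
        total = 0
        for part_name, part in (
            ("train", split.train),
            ("validation", split.validation),
            ("test", split.test),
        ):
            total += len(part)
            for rec in part.recordings.values():
                assert assignment[rec.participant_id] == part_name
        assert total == len(ds)

    def test_default_assignment_study_shape(self):
        pids = [f"P{i:02d}" for i in range(1, 11)]
        a = default_assignment(pids)
        assert [a[p] for p in pids] == ["train"] * 6 + ["validation"] * 2 + ["test"] * 2
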