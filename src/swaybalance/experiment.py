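"""End-to-end experiment: simulate/load, split, train all families, evaluate.

Produces a report shaped like the study's comparison table: one row per
representation (majority classifier, self-assessment, engineered features,
time series, image) with mean +/- SD accuracy and macro-AUROC across seeded
restarts, plus paired-t significance of every ML row against the majority
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .data_model import Dataset, DatasetSplit, default_assignment, filter_valid, split_by_participant
from .evaluation import (
    accuracy,
    compare_models,
    confusion_and_per_class,
    macro_auroc,
    mode_label,
    one_hot_scores,
)
from .kinematics import SwayTrajectory, feature_vector, integrate_angle
from .models import ModelSpec, TrainingConfig, predict_scores, train, tune_rf
from .models.core import train_with_weight_decay_grid
from .representations import (
    ChannelConfig,
    RasterBounds,
    augment_rotations,
    fit_bounds,
    fit_channel_stats,
    make_image_input,
    to_timeseries,
)
from .synthetic import SimulationConfig, simulate_dataset

__all__ = [
    "ExperimentConfig",
    "RepresentationData",
    "prepare_representation",
    "run_experiment",
]

REPRESENTATIONS = ("features", "timeseries", "image")

_FAMILY_OF = {"features": "random_forest", "timeseries": "cnn_1d", "image": "cnn_2d"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one full comparison run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    representations: tuple[str, ...] = REPRESENTATIONS
    n_seeds: int = 30
    training: TrainingConfig = field(default_factory=TrainingConfig)
    rf_grid: tuple[int, ...] = (1000,)
    channel_mode: str = "angle_velocity"
    augment: bool = True
    n_augment_copies: int = 3
    bounds_policy: str = "max_abs"
    tune_weight_decay: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RepresentationData:
    """Stacked model-ready arrays for one representation and split."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_val: np.ndarray
    y_val: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    groups: tuple[tuple[int, ...], ...]
    preprocessing: dict
    train_participants: list[str]


def _labels(ds: Dataset) -> np.ndarray:
    return np.asarray([mode_label(ds.ratings[rid]) for rid in ds.repetition_ids])


def _velocity_traj(rec) -> SwayTrajectory:
    return SwayTrajectory(pitch=rec.pitch_velocity, roll=rec.roll_velocity, kind="velocity")


def prepare_representation(
    split: DatasetSplit,
    representation: str,
    channel_mode: str = "angle_velocity",
    bounds_policy: str = "max_abs",
) -> RepresentationData:
    """Build stacked arrays for one representation.

    All fitted preprocessing state (channel statistics, raster bounds)
    derives from the training part only.
    """
    parts = {"train": split.train, "validation": split.validation, "test": split.test}
    ys = {k: _labels(ds) for k, ds in parts.items()}
    train_recs = [split.train.recordings[r] for r in split.train.repetition_ids]
    if not train_recs:
        raise ValueError("empty training split")
    pids = [r.participant_id for r in train_recs]

    if representation == "features":
        xs = {
            k: np.stack([feature_vector(ds.recordings[r]).values for r in ds.repetition_ids])
            if len(ds) else np.zeros((0, 11))
            for k, ds in parts.items()
        }
        groups: tuple[tuple[int, ...], ...] = ()
        preprocessing: dict = {}
    elif representation == "timeseries":
        ccfg = ChannelConfig(mode=channel_mode)
        stats = fit_channel_stats(train_recs, ccfg)
        target_len = train_recs[0].expected_samples
        xs = {
            k: np.stack(
                [to_timeseries(ds.recordings[r], ccfg, stats, target_len).channels
                 for r in ds.repetition_ids]
            ) if len(ds) else np.zeros((0, len(ccfg.channel_names), target_len))
            for k, ds in parts.items()
        }
        groups = ccfg.groups
        preprocessing = {
            "channel_mean": stats.mean,
            "channel_sd": stats.sd,
            "channel_mode": channel_mode,
            "target_len": target_len,
        }
    elif representation == "image":
        angle_trajs = [integrate_angle(r) for r in train_recs]
        vel_trajs = [_velocity_traj(r) for r in train_recs]
        angle_bounds = fit_bounds(angle_trajs, policy=bounds_policy)
        vel_bounds = fit_bounds(vel_trajs, policy=bounds_policy)
        xs = {
            k: np.stack(
                [make_image_input(ds.recordings[r], angle_bounds, vel_bounds).pixels
                 for r in ds.repetition_ids]
            ).astype(float) if len(ds) else np.zeros((0, 2, 60, 60))
            for k, ds in parts.items()
        }
        groups = ((0,), (1,))
        preprocessing = {
            "angle_bounds": [angle_bounds.pitch_halfwidth, angle_bounds.roll_halfwidth],
            "velocity_bounds": [vel_bounds.pitch_halfwidth, vel_bounds.roll_halfwidth],
            "bounds_policy": bounds_policy,
        }
    else:
        raise ValueError(f"unknown representation {representation!r}")
    return RepresentationData(
        x_train=xs["train"],
        y_train=ys["train"],
        x_val=xs["validation"],
        y_val=ys["validation"],
        x_test=xs["test"],
        y_test=ys["test"],
        groups=groups,
        preprocessing=preprocessing,
        train_participants=pids,
    )


def _augmented_training_images(
    split: DatasetSplit, data: RepresentationData, n_copies: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Training images plus rotated copies (training set only; labels carried over)."""
    ab = RasterBounds(*data.preprocessing["angle_bounds"])
    vb = RasterBounds(*data.preprocessing["velocity_bounds"])
    xs = [data.x_train]
    ys = [data.y_train]
    for i, rid in enumerate(split.train.repetition_ids):
        rec = split.train.recordings[rid]
        copies = augment_rotations(rec, ab, vb, n_copies=n_copies, seed=seed + i)
        xs.append(np.stack([c.pixels for c in copies]).astype(float))
        ys.append(np.full(n_copies, data.y_train[i]))
    return np.concatenate(xs), np.concatenate(ys)


def _fit_one(
    representation: str,
    split: DatasetSplit,
    data: RepresentationData,
    cfg: ExperimentConfig,
    seed: int,
    n_trees: int | None = None,
):
    tcfg = replace(cfg.training, seed=seed)
    family = _FAMILY_OF[representation]
    if family == "random_forest":
        spec = ModelSpec(family=family, n_trees=int(n_trees or cfg.rf_grid[0]))
        return train(spec, data.x_train, data.y_train, data.x_val, data.y_val, tcfg,
                     preprocessing=data.preprocessing)
    spec = ModelSpec(family=family)
    x_train, y_train = data.x_train, data.y_train
    if representation == "image" and cfg.augment:
        x_train, y_train = _augmented_training_images(split, data, cfg.n_augment_copies, seed)
    fit = train_with_weight_decay_grid if cfg.tune_weight_decay else train
    return fit(spec, x_train, y_train, data.x_val, data.y_val, tcfg,
               groups=data.groups, preprocessing=data.preprocessing)


def run_experiment(cfg: ExperimentConfig, dataset: Dataset | None = None) -> dict:
    """Run the full comparison protocol and return a table-shaped report.

    When ``dataset`` is omitted, one is simulated from ``cfg.simulation``.
    The report maps row name -> {accuracy_mean/sd, auroc_mean/sd, per-run
    values, confusion for the first run} plus significance annotations.
    """
    if dataset is None:
        dataset = simulate_dataset(cfg.simulation)
    dataset, exclusions = filter_valid(dataset, min_duration=cfg.simulation.duration)
    assignment = default_assignment(dataset.participant_ids)
    split = split_by_participant(dataset, assignment)
    y_train = _labels(split.train)
    y_test = _labels(split.test)

    report: dict = {
        "config": cfg.to_dict(),
        "exclusions": {"missing_label": exclusions.missing_label,
                       "premature": exclusions.premature},
        "split_sizes": {"train": len(split.train), "validation": len(split.validation),
                        "test": len(split.test)},
        "rows": {},
        "significance": {},
    }

    # --- baselines ---------------------------------------------------------
    train_mode = mode_label_from_array(y_train)
    majority_pred = np.full(y_test.shape, train_mode)
    majority_scores = np.full((y_test.size, 5), 0.2)
    majority_acc = accuracy(majority_pred, y_test)
    majority_auroc = macro_auroc(majority_scores, y_test)
    report["rows"]["majority_classifier"] = _row(
        [majority_acc] * cfg.n_seeds, [majority_auroc] * cfg.n_seeds,
        *confusion_and_per_class(majority_pred, y_test),
    )

    self_ratings = np.asarray(
        [split.test.ratings[r].self_rating or train_mode for r in split.test.repetition_ids]
    )
    self_acc = accuracy(self_ratings, y_test)
    self_auroc = macro_auroc(one_hot_scores(self_ratings), y_test)
    report["rows"]["self_assessment"] = _row(
        [self_acc] * cfg.n_seeds, [self_auroc] * cfg.n_seeds,
        *confusion_and_per_class(self_ratings, y_test),
    )

    # --- ML families -------------------------------------------------------
    for representation in cfg.representations:
        data = prepare_representation(
            split, representation, channel_mode=cfg.channel_mode,
            bounds_policy=cfg.bounds_policy,
        )
        n_trees = None
        if representation == "features" and len(cfg.rf_grid) > 1:
            n_trees = tune_rf(data.x_train, data.y_train, data.train_participants,
                              grid=cfg.rf_grid, seed=cfg.seed)
        accs, aurocs = [], []
        confusion = per_class = None
        for run in range(cfg.n_seeds):
            seed = cfg.seed * 10_000 + run
            model = _fit_one(representation, split, data, cfg, seed, n_trees)
            scores = predict_scores(model, data.x_test)
            preds = scores.argmax(axis=1) + 1
            accs.append(accuracy(preds, y_test))
            aurocs.append(macro_auroc(scores, y_test))
            if run == 0:
                confusion, per_class = confusion_and_per_class(preds, y_test)
        report["rows"][representation] = _row(accs, aurocs, confusion, per_class)

    # --- significance vs. the majority classifier --------------------------
    for representation in cfg.representations:
        row = report["rows"][representation]
        for metric, base in (("accuracy", majority_acc), ("auroc", majority_auroc)):
            try:
                cmp = compare_models(row[f"per_run_{metric}"], [base] * cfg.n_seeds)
            except ValueError:
                cmp = {"t_statistic": float("nan"), "p_value": float("nan"),
                       "significant": False}
            report["significance"][f"{representation}_vs_majority_{metric}"] = cmp
    return report


def mode_label_from_array(labels: np.ndarray) -> int:
    """Mode of a label array with the same tie rule as :func:`mode_label`."""
    from collections import Counter

    counts = Counter(int(v) for v in labels)
    top = max(counts.values())
    candidates = [v for v, c in counts.items() if c == top]
    mean = float(np.mean(labels))
    return max(candidates, key=lambda v: (-abs(v - mean), v))


def _row(accs, aurocs, confusion=None, per_class=None) -> dict:
    accs = [float(a) for a in accs]
    aurocs = [float(a) for a in aurocs]
    return {
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        "auroc_mean": float(np.mean(aurocs)),
        "auroc_sd": float(np.std(aurocs, ddof=1)) if len(aurocs) > 1 else 0.0,
        "per_run_accuracy": accs,
        "per_run_auroc": aurocs,
        "confusion": None if confusion is None else np.asarray(confusion).tolist(),
        "per_class_accuracy": per_class,
    }
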