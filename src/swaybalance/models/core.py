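"""Uniform model contract: build, train, tune, predict, serialize.

Three families share one interface:

* ``random_forest`` — scikit-learn ensemble over the 11-feature vectors,
  tree count chosen by leave-one-participant-out grid search;
* ``cnn_1d`` — one depth-wise grouped conv block (8 filters, kernel 3) over
  the standardized multichannel time series;
* ``cnn_2d`` — the same architecture with 3x3 kernels over the 60x60
  two-channel trajectory images.

CNN training minimizes cross-entropy with Adam (lr 1e-4, batch 32) for a
fixed epoch budget and returns the parameter snapshot with the best
validation macro-AUROC.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ..evaluation import macro_auroc
from .nn import (
    Adam,
    BatchNorm,
    Dense,
    Dropout,
    Flatten,
    GroupedConv1d,
    GroupedConv2d,
    MaxPool1d,
    MaxPool2d,
    ReLU,
    SequentialNet,
    cross_entropy_with_softmax,
)

__all__ = [
    "LABELS",
    "ModelSpec",
    "TrainingConfig",
    "ClassScores",
    "TrainedModel",
    "build_network",
    "train",
    "tune_rf",
    "predict",
    "predict_scores",
]

#: the ordinal class labels
LABELS: tuple[int, ...] = (1, 2, 3, 4, 5)

FAMILIES = ("random_forest", "cnn_1d", "cnn_2d")


@dataclass(frozen=True)
class ModelSpec:
    """Family plus family-specific hyperparameters."""

    family: str
    n_filters: int = 8
    kernel: int = 3
    fc_hidden: int = 64
    dropout: float = 0.5
    pool: int = 2
    n_trees: int = 1000

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; choose from {FAMILIES}")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings for the CNN families."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 2000
    weight_decay: float = 0.0
    weight_decay_grid: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("learning rate, batch size and epoch budget must be positive")


@dataclass(frozen=True)
class ClassScores:
    """Five class probabilities indexed by labels 1-5."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (5,):
            raise ValueError(f"expected 5 probabilities, got shape {p.shape}")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def predicted_label(self) -> int:
        return int(np.argmax(self.probs)) + 1


@dataclass
class TrainedModel:
    """A fitted model plus everything needed to reproduce its predictions."""

    spec: ModelSpec
    config: TrainingConfig
    net: SequentialNet | None = None
    forest: RandomForestClassifier | None = None
    forest_classes: tuple[int, ...] = ()
    preprocessing: dict = field(default_factory=dict)
    training_log: list[dict] = field(default_factory=list)
    best_epoch: int | None = None
    input_shape: tuple[int, ...] | None = None
    groups: tuple[tuple[int, ...], ...] = ()

    # -- persistence --------------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "spec": asdict(self.spec),
            "config": asdict(self.config),
            "best_epoch": self.best_epoch,
            "input_shape": self.input_shape,
            "groups": [list(g) for g in self.groups],
            "preprocessing": _jsonify(self.preprocessing),
        }
        with open(out_dir / "model.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        if self.training_log:
            import pandas as pd

            pd.DataFrame(self.training_log).to_csv(out_dir / "training_log.csv", index=False)
        if self.net is not None:
            state = self.net.get_state()
            np.savez(out_dir / "params.npz", **{f"p{i}": s for i, s in enumerate(state)})
        if self.forest is not None:
            with open(out_dir / "forest.pkl", "wb") as fh:
                pickle.dump({"forest": self.forest, "classes": self.forest_classes}, fh)
        return out_dir

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        model_dir = Path(model_dir)
        with open(model_dir / "model.json") as fh:
            meta = json.load(fh)
        spec = ModelSpec(**meta["spec"])
        cfg_d = dict(meta["config"])
        cfg_d["weight_decay_grid"] = tuple(cfg_d.get("weight_decay_grid", ()))
        config = TrainingConfig(**cfg_d)
        groups = tuple(tuple(g) for g in meta.get("groups", []))
        input_shape = tuple(meta["input_shape"]) if meta.get("input_shape") else None
        model = cls(
            spec=spec,
            config=config,
            preprocessing=meta.get("preprocessing", {}),
            best_epoch=meta.get("best_epoch"),
            input_shape=input_shape,
            groups=groups,
        )
        params_path = model_dir / "params.npz"
        if params_path.exists():
            assert input_shape is not None
            rng = np.random.Generator(np.random.PCG64(0))
            model.net = build_network(spec, input_shape, groups, rng)
            with np.load(params_path) as data:
                state = [data[f"p{i}"] for i in range(len(data.files))]
            model.net.set_state(state)
        forest_path = model_dir / "forest.pkl"
        if forest_path.exists():
            with open(forest_path, "rb") as fh:
                blob = pickle.load(fh)
            model.forest = blob["forest"]
            model.forest_classes = tuple(blob["classes"])
        return model


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def build_network(
    spec: ModelSpec,
    input_shape: tuple[int, ...],
    groups: Sequence[Sequence[int]],
    rng: np.random.Generator,
) -> SequentialNet:
    """Instantiate the CNN for ``spec`` given the per-example input shape.

    Both families share the block structure
    conv -> max-pool -> ReLU -> batch-norm -> flatten -> dense -> batch-norm
    -> ReLU -> dropout -> dense(5).
    """
    if spec.family == "cnn_1d":
        c, t = input_shape
        conv: object = GroupedConv1d(groups, spec.n_filters, spec.kernel, rng)
        pool: object = MaxPool1d(spec.pool)
        flat = spec.n_filters * ((t - spec.kernel + 1) // spec.pool)
    elif spec.family == "cnn_2d":
        c, h, w = input_shape
        conv = GroupedConv2d(groups, spec.n_filters, spec.kernel, rng)
        pool = MaxPool2d(spec.pool)
        flat = (
            spec.n_filters
            * ((h - spec.kernel + 1) // spec.pool)
            * ((w - spec.kernel + 1) // spec.pool)
        )
    else:
        raise ValueError(f"build_network only applies to CNN families, got {spec.family!r}")
    return SequentialNet(
        [
            conv,
            pool,
            ReLU(),
            BatchNorm(spec.n_filters),
            Flatten(),
            Dense(flat, spec.fc_hidden, rng),
            BatchNorm(spec.fc_hidden),
            ReLU(),
            Dropout(spec.dropout),
            Dense(spec.fc_hidden, len(LABELS), rng),
        ]
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _as_class_index(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if not np.isin(y, LABELS).all():
        raise ValueError("labels must lie in {1..5}")
    return y - 1


def train(
    spec: ModelSpec,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainingConfig,
    groups: Sequence[Sequence[int]] = ((0, 1), (2, 3)),
    preprocessing: dict | None = None,
) -> TrainedModel:
    """Fit one model; for CNNs, returns the best-validation-epoch snapshot.

    ``x_train``/``x_val`` are stacked representations: (N, 11) features,
    (N, C, T) series, or (N, 2, 60, 60) images.  ``y_*`` hold labels 1-5.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    if len(x_train) != len(y_train):
        raise ValueError("training inputs and labels differ in length")
    if spec.family == "random_forest":
        return _train_forest(spec, x_train, y_train, cfg, preprocessing)
    return _train_cnn(spec, x_train, y_train, x_val, y_val, cfg, groups, preprocessing)


def _train_forest(spec, x, y, cfg, preprocessing) -> TrainedModel:
    forest = RandomForestClassifier(n_estimators=spec.n_trees, random_state=cfg.seed, n_jobs=1)
    forest.fit(np.asarray(x, dtype=float), np.asarray(y, dtype=int))
    return TrainedModel(
        spec=spec,
        config=cfg,
        forest=forest,
        forest_classes=tuple(int(c) for c in forest.classes_),
        preprocessing=preprocessing or {},
        input_shape=tuple(np.asarray(x).shape[1:]),
    )


def _validation_metric(net: SequentialNet, x_val: np.ndarray, y_val: np.ndarray) -> float:
    if len(x_val) == 0:
        return float("nan")
    scores = net.predict_proba(np.asarray(x_val, dtype=float))
    try:
        return macro_auroc(scores, np.asarray(y_val, dtype=int))
    except ValueError:  # single-class validation set: metric undefined
        return float("nan")


def _train_cnn(spec, x_train, y_train, x_val, y_val, cfg, groups, preprocessing) -> TrainedModel:
    x = np.asarray(x_train, dtype=float)
    yi = _as_class_index(y_train)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    net = build_network(spec, x.shape[1:], groups, rng)
    opt = Adam(net.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    n = x.shape[0]
    log: list[dict] = []
    best_metric = -np.inf
    best_state = net.get_state()
    best_epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = net.forward(x[idx], training=True, rng=rng)
            loss, dlogits = cross_entropy_with_softmax(logits, yi[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (lr={cfg.learning_rate}, "
                    f"wd={cfg.weight_decay}); aborting"
                )
            net.backward(dlogits)
            opt.step(net.grads)
            epoch_loss += loss * len(idx)
        val_metric = _validation_metric(net, x_val, y_val)
        log.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "val_macro_auroc": val_metric}
        )
        if np.isfinite(val_metric) and val_metric > best_metric:
            best_metric = val_metric
            best_state = net.get_state()
            best_epoch = epoch
    if best_epoch == 0:  # validation metric never defined: keep final weights
        best_state = net.get_state()
        best_epoch = cfg.max_epochs
    net.set_state(best_state)
    return TrainedModel(
        spec=spec,
        config=cfg,
        net=net,
        preprocessing=preprocessing or {},
        training_log=log,
        best_epoch=best_epoch,
        input_shape=tuple(x.shape[1:]),
        groups=tuple(tuple(g) for g in groups),
    )


def train_with_weight_decay_grid(
    spec: ModelSpec,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainingConfig,
    groups: Sequence[Sequence[int]] = ((0, 1), (2, 3)),
    preprocessing: dict | None = None,
) -> TrainedModel:
    """Tune weight decay on validation macro-AUROC, then return the best model."""
    from dataclasses import replace

    best: TrainedModel | None = None
    best_metric = -np.inf
    for wd in cfg.weight_decay_grid:
        model = train(
            spec, x_train, y_train, x_val, y_val, replace(cfg, weight_decay=wd),
            groups=groups, preprocessing=preprocessing,
        )
        metric = max(
            (rec["val_macro_auroc"] for rec in model.training_log
             if np.isfinite(rec["val_macro_auroc"])),
            default=-np.inf,
        )
        if best is None or metric > best_metric:
            best, best_metric = model, metric
    assert best is not None
    return best


def tune_rf(
    x: np.ndarray,
    y: np.ndarray,
    participant_ids: Sequence[str],
    grid: Sequence[int] = (1000,),
    seed: int = 0,
) -> int:
    """Select the tree count by leave-one-participant-out cross-validation.

    For each grid value the held-out macro-AUROC is averaged over folds
    (one per training participant); ties break toward the smallest count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    pids = np.asarray(participant_ids)
    unique = np.unique(pids)
    if unique.size < 2:
        raise ValueError("leave-one-participant-out needs at least 2 participants")
    best_n, best_score = None, -np.inf
    for n_trees in grid:
        fold_scores = []
        for pid in unique:
            held = pids == pid
            if np.unique(y[held]).size < 2:
                continue  # AUROC undefined on a single-class fold
            forest = RandomForestClassifier(n_estimators=int(n_trees), random_state=seed, n_jobs=1)
            forest.fit(x[~held], y[~held])
            scores = _forest_scores(forest, x[held])
            fold_scores.append(macro_auroc(scores, y[held]))
        score = float(np.mean(fold_scores)) if fold_scores else -np.inf
        if score > best_score:
            best_n, best_score = int(n_trees), score
    assert best_n is not None
    return best_n


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _forest_scores(forest: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    """Map sklearn probabilities onto the full 5-label simplex (absent classes -> 0)."""
    proba = forest.predict_proba(np.asarray(x, dtype=float))
    out = np.zeros((proba.shape[0], len(LABELS)))
    for j, cls in enumerate(forest.classes_):
        out[:, int(cls) - 1] = proba[:, j]
    return out


def predict_scores(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    """Class-probability matrix (N, 5) for a batch of representations."""
    x = np.asarray(x, dtype=float)
    if model.input_shape is not None and tuple(x.shape[1:]) != tuple(model.input_shape):
        raise TypeError(
            f"representation shape {tuple(x.shape[1:])} does not match the model's "
            f"expected {tuple(model.input_shape)}"
        )
    if model.forest is not None:
        return _forest_scores(model.forest, x)
    assert model.net is not None
    return model.net.predict_proba(x)


def predict(model: TrainedModel, x: np.ndarray) -> ClassScores:
    """Scores for a single representation (deterministic; inference mode)."""
    batch = np.asarray(x, dtype=float)[None, ...]
    return ClassScores(probs=predict_scores(model, batch)[0])
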