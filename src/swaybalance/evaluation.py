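"""Ground-truth construction, metrics, baselines and rater-agreement statistics.

The ground-truth label for a repetition is the mode of its PT panel's
ratings (ties broken toward the rating closest to the panel mean, then
toward the more severe rating).  Models are scored by exact-match accuracy
and macro-averaged one-vs-rest AUROC; chance-corrected panel agreement uses
Krippendorff's alpha, implemented here via the coincidence matrix so it
handles variable panel sizes and missing ratings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import RatingSet

__all__ = [
    "EvaluationResult",
    "mode_label",
    "accuracy",
    "macro_auroc",
    "confusion_and_per_class",
    "random_rater_baseline",
    "krippendorff_alpha",
    "compare_models",
    "one_hot_scores",
]

N_CLASSES = 5


@dataclass
class EvaluationResult:
    """Aggregated metrics for one model over one or more runs."""

    accuracy: float
    macro_auroc: float
    per_class_accuracy: dict[int, float] = field(default_factory=dict)
    confusion: np.ndarray | None = None
    n_runs: int = 1
    per_run_accuracy: list[float] = field(default_factory=list)
    per_run_auroc: list[float] = field(default_factory=list)

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.per_run_accuracy, ddof=1)) if len(self.per_run_accuracy) > 1 else 0.0

    @property
    def auroc_sd(self) -> float:
        return float(np.std(self.per_run_auroc, ddof=1)) if len(self.per_run_auroc) > 1 else 0.0


def mode_label(rs: RatingSet) -> int:
    """Most frequent PT rating; ties go to the value closest to the panel
    mean, then to the higher (more severe) rating."""
    values = rs.values
    if not values:
        raise ValueError("cannot summarize an empty PT panel")
    counts = Counter(values)
    top = max(counts.values())
    candidates = [v for v, c in counts.items() if c == top]
    if len(candidates) == 1:
        return candidates[0]
    mean = float(np.mean(values))
    # closest to the mean wins; equidistant -> more severe
    return max(candidates, key=lambda v: (-abs(v - mean), v))


def accuracy(predictions: Sequence[int], truth: Sequence[int]) -> float:
    """Fraction of exact label matches."""
    p = np.asarray(predictions)
    t = np.asarray(truth)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return float(np.mean(p == t))


def _binary_auroc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Rank-based one-vs-rest AUROC; tied scores contribute one half."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = stats.rankdata(scores)  # average ranks handle ties
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def macro_auroc(scores: np.ndarray, truth: Sequence[int]) -> float:
    """Macro-averaged one-vs-rest AUROC.

    ``scores`` is (N, 5) with column ``c-1`` scoring class ``c``.  Classes
    absent from ``truth`` are excluded from the average; a single-class
    truth vector leaves the metric undefined.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    if s.ndim != 2 or s.shape[0] != t.size or s.shape[1] != N_CLASSES:
        raise ValueError(f"scores must be (n, {N_CLASSES}) aligned with truth")
    present = np.unique(t)
    if present.size < 2:
        raise ValueError("macro AUROC undefined for single-class truth")
    per_class = [_binary_auroc(s[:, c - 1], t == c) for c in present]
    return float(np.mean(per_class))


def confusion_and_per_class(
    predictions: Sequence[int], truth: Sequence[int]
) -> tuple[np.ndarray, dict[int, float]]:
    """5x5 confusion counts (rows = truth) and per-class recall."""
    p = np.asarray(predictions, dtype=int)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    if not (np.isin(p, range(1, 6)).all() and np.isin(t, range(1, 6)).all()):
        raise ValueError("labels must lie in {1..5}")
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for ti, pi in zip(t, p):
        conf[ti - 1, pi - 1] += 1
    per_class = {}
    for c in range(1, 6):
        n_c = conf[c - 1].sum()
        if n_c > 0:
            per_class[c] = float(conf[c - 1, c - 1] / n_c)
    return conf, per_class


def one_hot_scores(labels: Sequence[int]) -> np.ndarray:
    """One-hot (N, 5) score matrix for hard label predictions."""
    lab = np.asarray(labels, dtype=int)
    out = np.zeros((lab.size, N_CLASSES))
    out[np.arange(lab.size), lab - 1] = 1.0
    return out


def random_rater_baseline(
    ratings: Mapping[str, RatingSet],
    truth: Mapping[str, int],
    n_resamples: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Accuracy/AUROC of a randomly selected PT against the mode labels.

    Per resample one PT rating is drawn uniformly per repetition and
    treated as a hard (one-hot) prediction.  Returns means and SDs over
    ``n_resamples`` draws.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    rids = sorted(truth)
    panels = []
    for rid in rids:
        vals = ratings[rid].values
        if not vals:
            raise ValueError(f"repetition {rid} has no PT ratings")
        panels.append(np.asarray(vals))
    t = np.asarray([truth[rid] for rid in rids])
    accs, aurocs = [], []
    for _ in range(n_resamples):
        picks = np.asarray([panel[rng.integers(0, panel.size)] for panel in panels])
        accs.append(accuracy(picks, t))
        aurocs.append(macro_auroc(one_hot_scores(picks), t))
    return {
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_sd": float(np.std(accs)),
        "auroc_mean": float(np.mean(aurocs)),
        "auroc_sd": float(np.std(aurocs)),
    }


def krippendorff_alpha(ratings: np.ndarray, metric: str = "nominal") -> float:
    """Krippendorff's alpha for a units x raters matrix with missing entries (NaN).

    Computed from the coincidence matrix: ``1 - D_o / D_e`` where ``D_o``
    is the observed and ``D_e`` the expected disagreement under the chosen
    difference function (``nominal`` or ``ordinal``).
    """
    if metric not in ("nominal", "ordinal"):
        raise ValueError(f"unknown metric {metric!r}")
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D units x raters matrix")
    values = np.unique(m[np.isfinite(m)])
    if values.size == 0:
        raise ValueError("no ratings present")
    idx = {v: i for i, v in enumerate(values)}
    k = values.size
    coincidence = np.zeros((k, k))
    for row in m:
        vals = row[np.isfinite(row)]
        mu = vals.size
        if mu < 2:
            continue
        # ordered pairs of entries from different raters within the unit
        for a_pos in range(mu):
            for b_pos in range(mu):
                if a_pos != b_pos:
                    coincidence[idx[vals[a_pos]], idx[vals[b_pos]]] += 1.0 / (mu - 1)
    n_c = coincidence.sum(axis=1)
    n_total = n_c.sum()
    if n_total <= 1:
        raise ValueError("insufficient pairable ratings for Krippendorff's alpha")
    delta = _difference_matrix(values, n_c, metric)
    d_obs = float((coincidence * delta).sum()) / n_total
    d_exp = float((np.outer(n_c, n_c) * delta).sum()) / (n_total * (n_total - 1))
    if d_exp == 0.0:
        return 1.0
    return 1.0 - d_obs / d_exp


def _difference_matrix(values: np.ndarray, n_c: np.ndarray, metric: str) -> np.ndarray:
    k = values.size
    delta = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if metric == "nominal":
                delta[i, j] = 1.0
            else:  # ordinal: squared sum of marginals spanned by the two ranks
                lo, hi = min(i, j), max(i, j)
                delta[i, j] = (n_c[lo : hi + 1].sum() - (n_c[i] + n_c[j]) / 2.0) ** 2
    return delta


def compare_models(
    values_a: Sequence[float], values_b: Sequence[float], alpha: float = 0.05
) -> dict[str, float | bool]:
    """Two-sided paired t-test across matched runs (paired by seed)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length run vectors (>= 2 runs)")
    diff = a - b
    if np.allclose(diff, 0.0):
        return {"t_statistic": 0.0, "p_value": 1.0, "significant": False}
    if np.std(diff, ddof=1) == 0.0:
        # constant nonzero shift: the t statistic diverges
        sign = float(np.sign(diff.mean()))
        return {"t_statistic": sign * float("inf"), "p_value": 0.0,
                "significant": bool(0.0 < alpha)}
    res = stats.ttest_rel(a, b)
    return {
        "t_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
    }
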