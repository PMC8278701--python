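"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (loops, enumeration, closed forms)
and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def rms_brute(values) -> float:
    total = 0.0
    for v in values:
        total += float(v) * float(v)
    return math.sqrt(total / len(values))


def path_length_brute(pitch, roll) -> float:
    total = 0.0
    for i in range(1, len(pitch)):
        dp = float(pitch[i]) - float(pitch[i - 1])
        dr = float(roll[i]) - float(roll[i - 1])
        total += math.sqrt(dp * dp + dr * dr)
    return total


def binary_auroc_brute(scores, positive) -> float:
    """All-pairs concordance count with ties worth one half."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def macro_auroc_brute(scores, truth) -> float:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    aucs = []
    for c in sorted(set(truth.tolist())):
        aucs.append(binary_auroc_brute(scores[:, c - 1], truth == c))
    return float(np.mean(aucs))


def percentile_brute(values, p) -> float:
    """Linear-interpolation percentile on the sorted array (numpy's default rule)."""
    v = sorted(float(x) for x in values)
    if len(v) == 1:
        return v[0]
    h = (len(v) - 1) * p / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def krippendorff_brute(matrix, metric="nominal") -> float:
    """Definitional coincidence-matrix alpha, written independently."""
    matrix = np.asarray(matrix, dtype=float)
    vals = sorted({float(v) for row in matrix for v in row if np.isfinite(v)})
    index = {v: i for i, v in enumerate(vals)}
    k = len(vals)
    o = [[0.0] * k for _ in range(k)]
    for row in matrix:
        present = [float(v) for v in row if np.isfinite(v)]
        m = len(present)
        if m < 2:
            continue
        for a in range(m):
            for b in range(m):
                if a != b:
                    o[index[present[a]]][index[present[b]]] += 1.0 / (m - 1)
    n_c = [sum(o[i]) for i in range(k)]
    n = sum(n_c)

    def delta(i, j):
        if i == j:
            return 0.0
        if metric == "nominal":
            return 1.0
        lo, hi = min(i, j), max(i, j)
        return (sum(n_c[lo : hi + 1]) - (n_c[i] + n_c[j]) / 2.0) ** 2

    d_obs = sum(o[i][j] * delta(i, j) for i in range(k) for j in range(k)) / n
    d_exp = sum(
        n_c[i] * n_c[j] * delta(i, j) for i in range(k) for j in range(k)
    ) / (n * (n - 1))
    if d_exp == 0:
        return 1.0
    return 1.0 - d_obs / d_exp


def paired_t_brute(a, b):
    """Closed-form two-sided paired t-test (textbook formulas)."""
    from scipy.stats import t as t_dist

    d = [float(x) - float(y) for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t_stat = mean / math.sqrt(var / n)
    p = 2.0 * (1.0 - t_dist.cdf(abs(t_stat), df=n - 1))
    return t_stat, p


def random_rater_accuracy_exact(panels, truth) -> float:
    """Expected accuracy of a uniformly drawn rater, by full enumeration."""
    total = 0.0
    count = 0
    for combo in itertools.product(*panels):
        hits = sum(1 for pick, t in zip(combo, truth) if pick == t)
        total += hits / len(truth)
        count += 1
    return total / count


def diagonal_pixels(n: int) -> set[tuple[int, int]]:
    """Expected lit set for an exact corner-to-corner diagonal on an n x n grid."""
    return {(i, i) for i in range(n)}
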