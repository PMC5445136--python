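"""Independent brute-force oracles and fixture builders shared by tests.

These deliberately avoid numpy vectorization and the package's own code
paths so they can serve as independent references.
"""

import math
import statistics

import numpy as np

from painsig.protocol import LEVELS


def brute_force_features(x):
    """Loop-based reference for the 12 per-window statistics."""
    x = [float(v) for v in x]
    n = len(x)
    mu = sum(x) / n
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / (n - 1))
    th1 = sum(abs(x[i + 1] - x[i]) for i in range(n - 1)) / (n - 1)
    th2 = sum(abs(x[i + 2] - x[i]) for i in range(n - 2)) / (n - 2)
    f4 = th1 / sd if sd > 0 else 0.0
    f6 = th2 / sd if sd > 0 else 0.0
    mn, mx = min(x), max(x)
    med = statistics.median(x)
    return [mu, sd, th1, f4, th2, f6, mn, mx, mn / n, mx / n, mx - mn, med]


def brute_force_knn(train_X, train_y, query, k=3):
    """Exhaustive inverse-distance-weighted k-NN vote on raw features."""
    dists = [
        (math.sqrt(sum((a - b) ** 2 for a, b in zip(row, query))), label)
        for row, label in zip(train_X, train_y)
    ]
    dists.sort(key=lambda p: p[0])
    nearest = dists[:k]
    zero = [label for d, label in nearest if d == 0.0]
    if zero:
        return zero[0]
    votes = {}
    for d, label in nearest:
        votes[label] = votes.get(label, 0.0) + 1.0 / d
    return max(votes, key=lambda lb: votes[lb])


def make_planted_dataset(seed, n_per_class=60, n_features=36, n_informative=4,
                         effect=1.2):
    """Four balanced classes; the first ``n_informative`` columns carry a
    class-mean shift of ``effect`` per level rank, the rest are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat(LEVELS, n_per_class)
    X = rng.standard_normal((len(y), n_features))
    ranks = np.repeat(np.arange(len(LEVELS)), n_per_class)
    for j in range(n_informative):
        X[:, j] += effect * ranks
    perm = rng.permutation(len(y))
    planted = set(range(1, n_informative + 1))  # 1-based feature indices
    return X[perm], y[perm], planted


def make_blobs_4class(seed, n_per_class=40, n_features=6, separation=8.0):
    """Well-separated Gaussian blobs, one per pain level."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, separation, size=(len(LEVELS), n_features))
    X, y = [], []
    for c, lv in zip(centers, LEVELS):
        X.append(c + rng.standard_normal((n_per_class, n_features)))
        y += [lv] * n_per_class
    X = np.vstack(X)
    y = np.array(y)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
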