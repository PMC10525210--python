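"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive, loop-based re-derivations written from the
algorithm definitions, kept free of any code path they verify.
"""

from __future__ import annotations

import numpy as np


def knn1_brute(train_X, train_y, query_X):
    """All-pairs Euclidean scan; ties to the lowest training index."""
    train_X = np.asarray(train_X, float)
    query_X = np.asarray(query_X, float)
    out = []
    for q in query_X:
        best_j, best_d = 0, None
        for j, t in enumerate(train_X):
            dist = float(np.sqrt(((q - t) ** 2).sum()))
            if best_d is None or dist < best_d - 1e-300 or (dist < best_d):
                best_j, best_d = j, dist
        out.append(train_y[best_j])
    return np.asarray(out)


def relieff_brute(X, y, k_hits, scaled=True):
    """Exhaustive multiclass ReliefF: deterministic pass over every instance.

    Manhattan neighbor search on min-max-scaled features, k nearest hits and
    k nearest misses per other class (ties by ascending index), weight update
    -mean hit diff + prior-weighted mean miss diff, averaged over n.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, d = X.shape
    if scaled:
        lo, hi = X.min(axis=0), X.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        Xs = (X - lo) / rng
    else:
        Xs = X
    classes = sorted(set(y.tolist()))
    priors = {c: float(np.sum(y == c)) / n for c in classes}
    W = np.zeros(d)
    for i in range(n):
        for c in classes:
            cand = [j for j in range(n) if y[j] == c and j != i]
            cand.sort(key=lambda j: (float(np.abs(Xs[i] - Xs[j]).sum()), j))
            nearest = cand[:k_hits]
            mean_diff = np.mean([np.abs(Xs[i] - Xs[j]) for j in nearest], axis=0)
            if c == y[i]:
                W -= mean_diff
            else:
                W += priors[c] / (1.0 - priors[y[i]]) * mean_diff
    return W / n


def nca_objective_direct(Xs, y, w, lam):
    """Direct per-pair evaluation of the regularized leave-one-out objective."""
    n = Xs.shape[0]
    total = 0.0
    for i in range(n):
        kernels = {}
        for j in range(n):
            if j == i:
                continue
            dist = sum(w[r] ** 2 * abs(Xs[i, r] - Xs[j, r]) for r in range(Xs.shape[1]))
            kernels[j] = np.exp(-dist)
        denom = sum(kernels.values())
        if denom > 0:
            total += sum(k for j, k in kernels.items() if y[j] == y[i]) / denom
    return total - lam * sum(wi**2 for wi in w)


def mode_brute(votes):
    """Most frequent value; ties to the smallest value."""
    counts = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def chi2_brute(bins, classes):
    """Pearson chi-square of an observed bins-x-classes contingency table."""
    bins = np.asarray(bins)
    classes = np.asarray(classes)
    b_vals = sorted(set(bins.tolist()))
    c_vals = sorted(set(classes.tolist()))
    obs = np.array(
        [[np.sum((bins == b) & (classes == c)) for c in c_vals] for b in b_vals],
        dtype=float,
    )
    n = obs.sum()
    stat = 0.0
    for bi in range(obs.shape[0]):
        for ci in range(obs.shape[1]):
            exp = obs[bi].sum() * obs[:, ci].sum() / n
            if exp > 0:
                stat += (obs[bi, ci] - exp) ** 2 / exp
    return stat
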