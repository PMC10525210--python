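"""Filter-based feature selection: chi-square, ReliefF, and diagonal NCA.

Each selector assigns a per-feature informativeness score; ``select_top_k``
keeps the ``k`` highest-scoring columns (default 272, the pipeline's retained
feature count). All three scorers are deterministic given inputs and
parameters — no Monte-Carlo subsampling anywhere — so a fixed seed yields a
fixed selected set.

Scorers
-------
chi2
    Each continuous feature is discretized into equal-width bins over its
    observed range; the score is the Pearson chi-square statistic of the
    bins-by-classes contingency table (zero-count bins dropped). Constant
    features fall into a single bin and score exactly 0.
relieff
    Multiclass ReliefF with a deterministic pass over every instance. For
    instance i the k nearest same-class neighbors ("hits") and the k nearest
    neighbors in each other class ("misses") are found by Manhattan distance
    on min-max-scaled features. The weight of feature f is decreased by the
    mean hit difference and increased by the prior-weighted mean miss
    difference, averaged over all instances; scaled weights lie in [-1, 1].
nca
    Diagonal neighborhood component analysis: per-feature weights w maximize
    the expected leave-one-out correct-assignment count
    sum_i p_i - lambda * sum_r w_r^2, where p_ij is a softmax over
    exp(-sum_r w_r^2 |x_ir - x_jr|) for j != i and p_i sums p_ij over
    same-class j. Full-batch gradient ascent from w = 1 on internally
    z-scored features; the reported score is the final w_r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import FeatureMatrix

RETAINED_FEATURES = 272  # retained feature count per selected set

SELECTORS = ("nca", "relieff", "chi2")


class SelectionError(ValueError):
    pass


@dataclass
class FeatureRanking:
    selector: str
    scores: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.isfinite(self.scores).all():
            raise SelectionError(f"non-finite {self.selector} scores")


@dataclass
class SelectedFeatureSet:
    """Ordered retained column indices for one (feature matrix, selector) pair."""

    source: str
    selector: str
    indices: np.ndarray
    k: int

    @property
    def name(self) -> str:
        return f"{self.source}+{self.selector}"


def _as_xy(X: FeatureMatrix | np.ndarray, y: Optional[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, FeatureMatrix):
        return X.values, X.labels if y is None else np.asarray(y)
    if y is None:
        raise SelectionError("labels required when X is a bare array")
    return np.asarray(X, dtype=np.float64), np.asarray(y)


def chi2_scores(X, y=None, n_bins: int = 10) -> FeatureRanking:
    """Chi-square dependence between equal-width-binned features and the class."""
    Xv, yv = _as_xy(X, y)
    n, d = Xv.shape
    if n < 2:
        raise SelectionError("chi2 needs >= 2 samples")
    if n_bins < 2:
        raise SelectionError("n_bins must be >= 2")
    classes, y_idx = np.unique(yv, return_inverse=True)
    if classes.size < 2:
        raise SelectionError("chi2 undefined for a single class")
    scores = np.zeros(d)
    for j in range(d):
        col = Xv[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            continue  # one bin: no dependence, score 0
        bins = np.minimum(((col - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
        table = np.zeros((n_bins, classes.size))
        np.add.at(table, (bins, y_idx), 1)
        table = table[table.sum(axis=1) > 0]
        row = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = row * colsum / n
        scores[j] = ((table - expected) ** 2 / expected).sum()
    return FeatureRanking("chi2", scores, params={"n_bins": n_bins})


def _minmax_scale(Xv: np.ndarray) -> np.ndarray:
    lo = Xv.min(axis=0)
    rng = Xv.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (Xv - lo) / rng


def relieff_scores(X, y=None, k_hits: int = 10, scaled: bool = True) -> FeatureRanking:
    """Deterministic multiclass ReliefF over all instances.

    Neighbor ties are broken by ascending sample index. Requires every class
    to have more than ``k_hits`` members (so each instance has ``k_hits``
    same-class neighbors besides itself).
    """
    Xv, yv = _as_xy(X, y)
    n, d = Xv.shape
    if k_hits < 1:
        raise SelectionError("k_hits must be >= 1")
    classes, counts = np.unique(yv, return_counts=True)
    for c, cnt in zip(classes, counts):
        if cnt <= k_hits:
            raise SelectionError(
                f"class {c} has {cnt} members; ReliefF with k_hits={k_hits} "
                f"needs more than {k_hits}"
            )
    Xs = _minmax_scale(Xv) if scaled else Xv
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    dist = cdist(Xs, Xs, metric="cityblock")
    np.fill_diagonal(dist, np.inf)

    W = np.zeros(d)
    for i in range(n):
        ci = yv[i]
        for c in classes:
            mask = np.nonzero(yv == c)[0]
            if c == ci:
                mask = mask[mask != i]
            # stable sort on (distance, index): lexsort's last key is primary
            order = mask[np.lexsort((mask, dist[i, mask]))][:k_hits]
            mean_diff = np.abs(Xs[order] - Xs[i]).mean(axis=0)
            if c == ci:
                W -= mean_diff
            else:
                W += priors[c] / (1.0 - priors[ci]) * mean_diff
    W /= n
    return FeatureRanking("relieff", W, params={"k_hits": k_hits, "scaled": scaled})


def nca_objective(Xs: np.ndarray, yv: np.ndarray, w: np.ndarray, lam: float) -> float:
    """Regularized leave-one-out objective sum_i p_i - lam * ||w||^2.

    Direct evaluation; used by the optimizer and exposed for verification.
    """
    n = Xs.shape[0]
    w2 = w**2
    dists = (np.abs(Xs[:, None, :] - Xs[None, :, :]) * w2).sum(axis=2)
    K = np.exp(-dists)
    np.fill_diagonal(K, 0.0)
    denom = K.sum(axis=1)
    same = (yv[:, None] == yv[None, :]) & ~np.eye(n, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.where(denom > 0, (K * same).sum(axis=1) / denom, 0.0)
    return float(p_i.sum() - lam * (w2).sum())


def nca_weights(
    X,
    y=None,
    lam: Optional[float] = None,
    learn_rate: float = 0.2,
    max_iter: int = 100,
    seed: int = 0,
) -> FeatureRanking:
    """Diagonal-NCA feature weights by full-batch gradient ascent.

    Features are z-scored internally. Initialization is the deterministic
    all-ones vector (``seed`` is recorded for provenance only). The step size
    is ``learn_rate / n`` so the update scale is sample-size free. Default
    regularization is ``lam = 1/n``. Scores are the squared final weights;
    zero-variance columns are assigned score 0 (they contribute to no
    distance and carry no class information).
    """
    Xv, yv = _as_xy(X, y)
    n, d = Xv.shape
    if n < 3:
        raise SelectionError("nca needs >= 3 samples")
    lam = 1.0 / n if lam is None else float(lam)
    if lam < 0:
        raise SelectionError("lambda must be >= 0")

    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    constant = sd == 0
    sd[constant] = 1.0
    Xs = (Xv - mu) / sd

    # The |x_i - x_j| tensor is symmetric, so only the i < j pairs are
    # stored (float32: it only carries pairwise distances and gradient
    # accumulations, whose ~1e-7 relative error is far below ranking
    # resolution). Falls back to per-row chunks when too large for memory.
    n_pairs = n * (n - 1) // 2
    use_tensor = n_pairs * d <= 200_000_000
    if use_tensor:
        iu = np.triu_indices(n, k=1)
        Dp = np.abs(Xs[iu[0]] - Xs[iu[1]]).astype(np.float32)
    same = yv[:, None] == yv[None, :]
    np.fill_diagonal(same, False)

    # fixed step learn_rate / n keeps the update scale sample-size free; the
    # cap keeps the regularizer decay factor |1 - 2*lam*step| < 1 so strongly
    # regularized runs contract to zero instead of oscillating
    step = learn_rate / n
    if lam > 0:
        step = min(step, 0.9 / (2.0 * lam))

    w = np.ones(d)
    for _ in range(max_iter):
        w2 = w**2
        if use_tensor:
            dvec = (Dp @ w2.astype(np.float32)).astype(np.float64)
            dists = np.zeros((n, n))
            dists[iu] = dvec
            dists += dists.T
        else:
            dists = np.empty((n, n))
            for i in range(n):
                dists[i] = np.abs(Xs - Xs[i]) @ w2
        K = np.exp(-dists)
        np.fill_diagonal(K, 0.0)
        denom = K.sum(axis=1)
        if not np.isfinite(denom).all():
            raise SelectionError(
                "non-finite NCA objective; check feature standardization"
            )
        safe = np.where(denom > 0, denom, 1.0)
        P = K / safe[:, None]  # p_ij
        p_i = (P * same).sum(axis=1)
        # gradient of sum_i p_i wrt w_r:
        #   2 w_r * sum_i [ p_i * sum_l p_il D_ilr - sum_{j in C_i} p_ij D_ijr ]
        C = P * p_i[:, None] - P * same  # per-(i, j) coefficient of D_ijr
        if use_tensor:
            csym = (C + C.T)[iu].astype(np.float32)
            grad_core = (csym @ Dp).astype(np.float64)
        else:
            grad_core = np.zeros(d)
            for i in range(n):
                grad_core += C[i] @ np.abs(Xs - Xs[i])
        grad = 2.0 * w * grad_core - 2.0 * lam * w
        w = w + step * grad
    scores = w**2
    scores[constant] = 0.0  # zero-variance columns carry no information
    return FeatureRanking(
        "nca",
        scores,
        params={"lambda": lam, "learn_rate": learn_rate, "max_iter": max_iter},
        seed=seed,
    )


_SCORERS = {"chi2": chi2_scores, "relieff": relieff_scores, "nca": nca_weights}


def score_features(X, y=None, selector: str = "nca", **params) -> FeatureRanking:
    if selector not in _SCORERS:
        raise SelectionError(f"unknown selector '{selector}'; valid: {sorted(_SCORERS)}")
    return _SCORERS[selector](X, y, **params)


def select_top_k(
    ranking: FeatureRanking, X: FeatureMatrix, k: int = RETAINED_FEATURES
) -> tuple[SelectedFeatureSet, FeatureMatrix]:
    """Keep the min(k, d) highest-scoring columns, ties broken by ascending index.

    The reduced matrix's columns are ordered by descending score.
    """
    if k <= 0:
        raise SelectionError("k must be positive")
    d = X.d
    if ranking.scores.size != d:
        raise SelectionError(
            f"ranking length {ranking.scores.size} != feature count {d}"
        )
    kept = min(k, d)
    # stable sort on descending score; stability gives the ascending-index tie-break
    order = np.argsort(-ranking.scores, kind="stable")[:kept]
    sel = SelectedFeatureSet(
        source=X.source, selector=ranking.selector, indices=order, k=kept
    )
    reduced = FeatureMatrix(
        values=X.values[:, order],
        sample_ids=X.sample_ids,
        labels=X.labels,
        source=f"{X.source}+{ranking.selector}",
    )
    return sel, reduced
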