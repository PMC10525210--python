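"""Standardized 1-nearest-neighbor classification under stratified k-fold CV.

The classifier is deliberately minimal: one neighbor, Euclidean distance,
uniform weighting, features z-scored on the training portion of each fold.
``cross_val_predict`` returns the out-of-fold prediction vector — every
sample predicted exactly once, while held out — which is what the voting
stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import FeatureMatrix


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    grouped: bool = False
    standardize_mode: str = "per-fold"  # or "global" for whole-dataset z-scoring


@dataclass
class PredictionVector:
    """Out-of-fold predicted class codes for every sample, with provenance."""

    labels: np.ndarray
    provenance: str
    accuracy: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)


@dataclass
class StandardizeParams:
    mean: np.ndarray
    std: np.ndarray  # population std; zero-variance columns stored as 0


def standardize(train: np.ndarray) -> tuple[StandardizeParams, np.ndarray]:
    """Fit per-feature z-scoring on *train* (population std) and apply it.

    Zero-variance columns map to 0 rather than dividing by zero.
    """
    train = np.asarray(train, dtype=np.float64)
    if train.size == 0:
        raise ClassificationError("empty training matrix")
    params = StandardizeParams(mean=train.mean(axis=0), std=train.std(axis=0))
    return params, apply_standardize(params, train)


def apply_standardize(params: StandardizeParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    safe = np.where(params.std > 0, params.std, 1.0)
    out = (X - params.mean) / safe
    out[:, params.std == 0] = 0.0
    return out


def knn1_predict(train_X: np.ndarray, train_y: np.ndarray, query_X: np.ndarray) -> np.ndarray:
    """Label of the Euclidean-nearest training row; ties go to the lowest row index."""
    train_X = np.asarray(train_X, dtype=np.float64)
    query_X = np.asarray(query_X, dtype=np.float64)
    if train_X.shape[0] == 0:
        raise ClassificationError("empty training set")
    if train_X.shape[1] != query_X.shape[1]:
        raise ClassificationError(
            f"dimension mismatch: train d={train_X.shape[1]}, query d={query_X.shape[1]}"
        )
    dist = cdist(query_X, train_X, metric="euclidean")
    nearest = dist.argmin(axis=1)  # argmin returns the first (lowest-index) minimum
    return np.asarray(train_y)[nearest]


def make_folds(y: np.ndarray, cfg: CVConfig, groups: Optional[list[str]] = None) -> np.ndarray:
    """Stratified fold assignment: seeded shuffle within class, then round-robin.

    With ``cfg.grouped`` and group ids, whole groups (labeled by their first
    sample's class) are shuffled and dealt round-robin, so samples sharing a
    group always land in the same fold.
    """
    y = np.asarray(y)
    n = y.size
    if cfg.n_folds < 2:
        raise ClassificationError("n_folds must be >= 2")
    if cfg.n_folds > n:
        raise ClassificationError(f"n_folds={cfg.n_folds} exceeds n={n}")
    rng = np.random.default_rng(cfg.seed)
    folds = np.empty(n, dtype=np.int64)

    if cfg.grouped and groups is not None:
        group_ids = list(dict.fromkeys(groups))  # first-appearance order
        g_label = {g: y[groups.index(g)] for g in group_ids}
        counter = 0
        for cls in np.unique(y):
            members = [g for g in group_ids if g_label[g] == cls]
            members = [members[i] for i in rng.permutation(len(members))]
            for g in members:
                idx = [i for i, gg in enumerate(groups) if gg == g]
                folds[idx] = counter % cfg.n_folds
                counter += 1
        return folds

    if cfg.stratified:
        # per-class round-robin keeps every fold's class count within one
        # sample of n_c / n_folds
        for cls in np.unique(y):
            idx = np.nonzero(y == cls)[0]
            idx = idx[rng.permutation(idx.size)]
            folds[idx] = np.arange(idx.size) % cfg.n_folds
        return folds
    perm = rng.permutation(n)
    for pos, i in enumerate(perm):
        folds[i] = pos % cfg.n_folds
    return folds


def cross_val_predict(
    X_selected: FeatureMatrix | np.ndarray,
    y: Optional[np.ndarray] = None,
    cfg: CVConfig = CVConfig(),
    groups: Optional[list[str]] = None,
    provenance: Optional[str] = None,
) -> PredictionVector:
    """Out-of-fold 1-NN predictions: standardize on train folds, predict held-out.

    Standardization parameters are computed from the training folds only, so
    held-out samples never influence the transform applied to them.
    """
    if isinstance(X_selected, FeatureMatrix):
        Xv = X_selected.values
        yv = X_selected.labels if y is None else np.asarray(y)
        provenance = provenance or X_selected.source
    else:
        Xv = np.asarray(X_selected, dtype=np.float64)
        if y is None:
            raise ClassificationError("labels required")
        yv = np.asarray(y)
        provenance = provenance or "array"

    folds = make_folds(yv, cfg, groups=groups)
    pred = np.empty(yv.size, dtype=yv.dtype)

    if cfg.standardize_mode == "global":
        _, Xg = standardize(Xv)
        for f in range(cfg.n_folds):
            test = folds == f
            pred[test] = knn1_predict(Xg[~test], yv[~test], Xg[test])
    else:
        for f in range(cfg.n_folds):
            test = folds == f
            params, train_z = standardize(Xv[~test])
            test_z = apply_standardize(params, Xv[test])
            pred[test] = knn1_predict(train_z, yv[~test], test_z)

    acc = float(np.mean(pred == yv))
    return PredictionVector(labels=pred, provenance=provenance, accuracy=acc)


def holdout_predict(
    X: np.ndarray, y: np.ndarray, test_fraction: float, seed: int = 0
) -> PredictionVector:
    """Single stratified holdout split (supported as an alternate validation scheme)."""
    if not 0 < test_fraction < 1:
        raise ClassificationError("test_fraction must be in (0, 1)")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(y.size, dtype=bool)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        n_test = max(1, int(round(test_fraction * idx.size)))
        test_mask[idx[:n_test]] = True
    params, train_z = standardize(np.asarray(X)[~test_mask])
    test_z = apply_standardize(params, np.asarray(X)[test_mask])
    pred = knn1_predict(train_z, y[~test_mask], test_z)
    acc = float(np.mean(pred == y[test_mask]))
    labels = y.copy()
    labels[test_mask] = pred
    return PredictionVector(labels=labels, provenance=f"holdout{test_fraction}", accuracy=acc)
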