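"""Iterative majority voting (IMV) and best-outcome selection.

The classifier stage yields one out-of-fold prediction vector per selected
feature set (18 at the default configuration). IMV sorts those vectors by
accuracy, then for each prefix size r in [r_min, r_max] takes the per-sample
mode of the top r vectors, yielding r_max - r_min + 1 voted outcomes (16 at
the defaults, loop 3..18). The final output is the maximum-accuracy
candidate among all classifier-wise and voted outcomes (34 at the defaults);
a config switch restricts the candidate pool to the voted outcomes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .classification import PredictionVector


class FusionError(ValueError):
    pass


@dataclass
class VotedOutcome:
    r: int
    labels: np.ndarray
    accuracy: float
    sources: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"imv_r{self.r}"


@dataclass
class PipelineResult:
    """All candidate outcomes plus the selected best and its metric panel."""

    classifier_wise: list[PredictionVector]
    voted: list[VotedOutcome]
    best_kind: str  # "classifier" or "voted"
    best_index: int
    metrics: Optional[object] = None  # ClassMetrics of the best outcome
    confusion: Optional[object] = None
    config: dict = field(default_factory=dict)

    @property
    def best(self) -> PredictionVector | VotedOutcome:
        pool = self.classifier_wise if self.best_kind == "classifier" else self.voted
        return pool[self.best_index]

    @property
    def best_accuracy(self) -> float:
        return self.best.accuracy

    @property
    def best_name(self) -> str:
        b = self.best
        return b.provenance if isinstance(b, PredictionVector) else b.name

    @property
    def n_candidates(self) -> int:
        return len(self.classifier_wise) + len(self.voted)


def sort_by_accuracy(preds: list[PredictionVector]) -> list[PredictionVector]:
    """Stable descending sort by accuracy; ties keep the input order."""
    if not preds:
        raise FusionError("no prediction vectors")
    n = preds[0].labels.size
    if any(p.labels.size != n for p in preds):
        raise FusionError("prediction vectors differ in length")
    return sorted(preds, key=lambda p: -p.accuracy)  # sorted() is stable


def majority_vote(preds_subset: list[PredictionVector]) -> np.ndarray:
    """Per-sample mode of the given vectors; ties go to the smallest class code."""
    if not preds_subset:
        raise FusionError("majority_vote needs >= 1 vectors")
    stack = np.stack([p.labels for p in preds_subset])  # r x n
    codes = np.unique(stack)
    # counts per (code, sample); argmax picks the first = smallest code on ties
    counts = np.stack([(stack == c).sum(axis=0) for c in codes])
    return codes[counts.argmax(axis=0)]


def imv(
    preds: list[PredictionVector],
    truth: np.ndarray,
    r_min: int = 3,
    r_max: int = 18,
) -> list[VotedOutcome]:
    """Voted outcomes for every prefix size r in [r_min, r_max]."""
    if r_min < 2:
        raise FusionError("r_min must be >= 2")
    if r_max < r_min:
        raise FusionError("r_max must be >= r_min")
    if len(preds) < r_min:
        raise FusionError(f"need >= {r_min} prediction vectors, got {len(preds)}")
    if r_max > len(preds):
        raise FusionError(f"r_max={r_max} exceeds available vectors ({len(preds)})")
    truth = np.asarray(truth)
    ranked = sort_by_accuracy(preds)
    out = []
    for r in range(r_min, r_max + 1):
        subset = ranked[:r]
        labels = majority_vote(subset)
        acc = float(np.mean(labels == truth))
        out.append(
            VotedOutcome(
                r=r, labels=labels, accuracy=acc, sources=[p.provenance for p in subset]
            )
        )
    return out


def select_best(
    classifier_wise: list[PredictionVector],
    voted: list[VotedOutcome],
    truth: np.ndarray,
    candidate_pool: str = "all",
) -> PipelineResult:
    """Pick the maximum-accuracy candidate across the requested pool.

    Ties prefer a voted outcome over a classifier-wise one, then the smaller
    r among voted, then the earlier classifier-wise index.
    """
    if candidate_pool not in ("all", "voted"):
        raise FusionError("candidate_pool must be 'all' or 'voted'")
    candidates: list[tuple[float, int, str, int]] = []
    # rank key encodes the tie preference: voted first (0), then position
    for i, v in enumerate(voted):
        candidates.append((v.accuracy, 0, "voted", i))
    if candidate_pool == "all":
        for i, p in enumerate(classifier_wise):
            candidates.append((p.accuracy, 1, "classifier", i))
    if not candidates:
        raise FusionError("no candidate outcomes")
    best = min(candidates, key=lambda c: (-c[0], c[1], c[3]))
    return PipelineResult(
        classifier_wise=classifier_wise,
        voted=voted,
        best_kind=best[2],
        best_index=best[3],
    )
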