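"""End-to-end orchestration: extract, select, classify, vote, report.

``run`` executes the whole pipeline on an image directory or a precomputed
feature table and returns a :class:`~asnet.fusion.PipelineResult` holding
every candidate outcome. At the default configuration that is 6 feature
matrices x 3 selectors = 18 prediction vectors, 16 voted outcomes (loop
3..18), and the best of all 34 candidates. When fewer matrices are
available (e.g., a single feature table) the voting loop upper bound clamps
to the number of prediction vectors.

One global seed fans out to per-stage seeds by fixed offsets so stages are
reproducible yet independent.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import data_io, feature_extraction, feature_selection, fusion, metrics
from .classification import CVConfig, cross_val_predict
from .data_io import DatasetManifest, FeatureMatrix
from .fusion import PipelineResult

logger = logging.getLogger("asnet")

# fixed per-stage seed offsets
_SEED_EXTRACT = 101
_SEED_CV = 211


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    data: Optional[str] = None  # image directory (class subdirs)
    feature_table: Optional[str] = None  # alternative input
    mode: str = "toy"  # "toy" | "pretrained"
    selectors: tuple[str, ...] = feature_selection.SELECTORS
    k: int = feature_selection.RETAINED_FEATURES
    chi2_bins: int = 10
    relieff_k_hits: int = 10
    nca_lambda: Optional[float] = None  # default 1/n
    nca_learn_rate: float = 0.2
    nca_max_iter: int = 100
    n_folds: int = 10
    grouped: bool = False
    standardize_mode: str = "per-fold"
    r_min: int = 3
    r_max: int = 18
    candidate_pool: str = "all"  # "all" (classifier-wise + voted) or "voted"
    taps: Optional[tuple[int, ...]] = None  # subset of the six registered taps
    selection_scope: str = "full"  # "full" dataset (protocol default) or "nested"
    batch_size: int = 8
    seed: int = 0
    out: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


def _score(cfg: RunConfig, fm: FeatureMatrix, selector: str) -> feature_selection.FeatureRanking:
    if selector == "chi2":
        return feature_selection.chi2_scores(fm, n_bins=cfg.chi2_bins)
    if selector == "relieff":
        counts = np.bincount(fm.labels)[1:]
        # clamp so the smallest class still has k_hits same-class neighbors
        k_hits = min(cfg.relieff_k_hits, int(counts[counts > 0].min()) - 1)
        return feature_selection.relieff_scores(fm, k_hits=max(1, k_hits))
    if selector == "nca":
        return feature_selection.nca_weights(
            fm,
            lam=cfg.nca_lambda,
            learn_rate=cfg.nca_learn_rate,
            max_iter=cfg.nca_max_iter,
            seed=cfg.seed,
        )
    raise PipelineError(f"unknown selector '{selector}'")


def _load_matrices(cfg: RunConfig) -> tuple[list[FeatureMatrix], np.ndarray, list[str]]:
    if cfg.feature_table:
        fm = data_io.read_feature_table(cfg.feature_table)
        return [fm], fm.labels, [f"class{c}" for c in np.unique(fm.labels)]
    if not cfg.data:
        raise PipelineError("config needs 'data' (image dir) or 'feature_table'")
    manifest = data_io.load_manifest(cfg.data, layout="class-subdirs")
    specs = feature_extraction.default_specs(mode=cfg.mode, seed=cfg.seed + _SEED_EXTRACT)
    if cfg.taps is not None:
        specs = [specs[i] for i in cfg.taps]
    mats = feature_extraction.extract_all(
        manifest, specs=specs, batch_size=cfg.batch_size
    )
    return mats, manifest.label_codes(), manifest.class_names


def run(cfg: RunConfig) -> PipelineResult:
    """Execute the full pipeline and (optionally) write reports to ``cfg.out``."""
    matrices, truth, class_names = _load_matrices(cfg)
    logger.info("extracted %d feature matrices (n=%d)", len(matrices), truth.size)

    cv_cfg = CVConfig(
        n_folds=cfg.n_folds,
        seed=cfg.seed + _SEED_CV,
        grouped=cfg.grouped,
        standardize_mode=cfg.standardize_mode,
    )

    preds = []
    selected_sets = []
    for fm in matrices:
        for selector in cfg.selectors:
            if cfg.selection_scope == "nested":
                pv = _nested_cv_predict(cfg, fm, selector, cv_cfg)
                selected_sets.append(None)
            else:
                ranking = _score(cfg, fm, selector)
                sel, reduced = feature_selection.select_top_k(ranking, fm, k=cfg.k)
                selected_sets.append(sel)
                pv = cross_val_predict(reduced, cfg=cv_cfg)
            logger.info("%s + %s: accuracy %.4f", fm.source, selector, pv.accuracy)
            preds.append(pv)

    r_max = min(cfg.r_max, len(preds))
    r_min = min(cfg.r_min, r_max)
    voted = fusion.imv(preds, truth, r_min=r_min, r_max=r_max)
    result = fusion.select_best(preds, voted, truth, candidate_pool=cfg.candidate_pool)

    best_labels = result.best.labels
    cm = metrics.confusion(truth, best_labels, class_names)
    result.confusion = cm
    result.metrics = metrics.panel(cm)
    result.config = cfg.to_dict()
    result.config["counts"] = {
        "matrices": len(matrices),
        "selected_sets": len([s for s in selected_sets if s is not None]) or len(preds),
        "prediction_vectors": len(preds),
        "voted_outcomes": len(voted),
        "candidates": result.n_candidates,
    }
    if cfg.out:
        write_reports(result, cfg.out)
    return result


def _nested_cv_predict(cfg: RunConfig, fm: FeatureMatrix, selector: str, cv_cfg: CVConfig):
    """Leakage-safe mode: rank and select features inside each training fold."""
    from .classification import (
        apply_standardize,
        knn1_predict,
        make_folds,
        standardize,
    )

    folds = make_folds(fm.labels, cv_cfg)
    pred = np.empty(fm.n, dtype=np.int64)
    for f in range(cv_cfg.n_folds):
        test = folds == f
        train_fm = FeatureMatrix(
            values=fm.values[~test],
            sample_ids=[s for s, m in zip(fm.sample_ids, ~test) if m],
            labels=fm.labels[~test],
            source=fm.source,
        )
        ranking = _score(cfg, train_fm, selector)
        sel, _ = feature_selection.select_top_k(ranking, train_fm, k=cfg.k)
        cols = sel.indices
        params, train_z = standardize(fm.values[np.ix_(~test, cols)])
        test_z = apply_standardize(params, fm.values[np.ix_(test, cols)])
        pred[test] = knn1_predict(train_z, fm.labels[~test], test_z)
    acc = float(np.mean(pred == fm.labels))
    from .classification import PredictionVector

    return PredictionVector(labels=pred, provenance=f"{fm.source}+{selector}(nested)", accuracy=acc)


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def _split_provenance(provenance: str) -> tuple[str, str, str]:
    """(backbone, layer, selector) from a 'backbone/layer+selector' id."""
    head, _, selector = provenance.rpartition("+")
    backbone, _, layer = head.partition("/")
    if backbone == "toy" and "." in layer:
        backbone, _, layer = layer.partition(".")
        backbone = f"toy:{backbone}"
    return backbone, layer, selector


def report_table2(result: PipelineResult) -> list[dict]:
    """Classifier-wise accuracy table: one row per (backbone, layer, selector)."""
    if not result.classifier_wise:
        raise PipelineError("empty result")
    best_name = result.best_name
    rows = []
    for i, p in enumerate(result.classifier_wise, start=1):
        backbone, layer, selector = _split_provenance(p.provenance)
        rows.append(
            {
                "no": i,
                "backbone": backbone,
                "layer": layer,
                "selector": selector,
                "accuracy_pct": metrics.percent(p.accuracy),
                "best": p.provenance == best_name,
            }
        )
    return rows


def report_table3(result: PipelineResult) -> list[dict]:
    """Per-class metric panel of the best outcome (accuracy repeated per row)."""
    if result.metrics is None:
        raise PipelineError("result has no metric panel")
    rows = []
    for row in result.metrics.per_class:
        rows.append(
            {
                "class": row.name,
                "accuracy_pct": metrics.percent(result.metrics.accuracy),
                "recall_pct": metrics.percent(row.recall),
                "precision_pct": metrics.percent(row.precision),
                "f1_pct": metrics.percent(row.f1),
            }
        )
    return rows


def write_reports(result: PipelineResult, out_dir: str | Path) -> None:
    """JSON report + classifier-wise and metric-panel CSVs + resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t2 = report_table2(result)
    with open(out / "classifier_wise.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(t2[0].keys()))
        writer.writeheader()
        writer.writerows(t2)

    t3 = report_table3(result)
    with open(out / "metric_panel.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(t3[0].keys()))
        writer.writeheader()
        writer.writerows(t3)

    report = {
        "best_candidate": result.best_name,
        "best_accuracy_pct": metrics.percent(result.best_accuracy),
        "confusion": result.confusion.counts.tolist(),
        **metrics.panel_report(result.metrics),
        "voted": [
            {"r": v.r, "accuracy_pct": metrics.percent(v.accuracy)} for v in result.voted
        ],
        "classifier_wise": [
            {"id": p.provenance, "accuracy_pct": metrics.percent(p.accuracy)}
            for p in result.classifier_wise
        ],
        "counts": result.config.get("counts", {}),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "config.json").write_text(json.dumps(result.config, indent=2, sort_keys=True))
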