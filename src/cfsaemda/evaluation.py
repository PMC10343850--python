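"""Metrics, the train/CV protocol, and leave-one-disease-out case studies.

Threshold metrics follow the standard confusion-matrix definitions (accuracy,
precision, sensitivity, specificity, MCC, F1) at a 0.5 cut-off; MCC is defined
as 0 when its denominator vanishes.  Ranking quality is measured by the areas
under the ROC curve (trapezoidal, tie-aware — equal to the Mann-Whitney
statistic with ties counted one half) and the precision-recall curve
(step-wise summation, i.e. average precision).

The evaluation protocol splits the balanced sample 8:2 into training and test
sets, runs stratified 4-fold cross-validation on the training set (fitting
the full stacked-autoencoder + cascade pipeline per fold), and fits once on
the whole training set for the test-set report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import AssociationMatrix, DiseaseOntology, SimilarityMatrix
from .features import PairFeatureSet, balanced_pair_sample, build_pair_features, kfold_partition, split_train_test
from .pipeline import PipelineConfig, fit_pipeline, pipeline_scores
from .similarity import integrated_similarities

__all__ = [
    "MetricsReport",
    "RankedPredictions",
    "confusion_metrics",
    "roc_auc",
    "pr_auc",
    "run_protocol",
    "case_study",
]


@dataclass
class MetricsReport:
    """Confusion counts plus the derived scalar metrics at one threshold."""

    TP: int
    TN: int
    FP: int
    FN: int
    acc: float
    pre: float
    sen: float
    spe: float
    mcc: float
    f1: float
    auc: float
    aupr: float
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return asdict(self)


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve; errors when only one class is present."""
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC needs both classes")
    return float(roc_auc_score(y, scores))


def pr_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise summation."""
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("AUPR needs both classes")
    return float(average_precision_score(y, scores))


def confusion_metrics(y: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """Evaluate all threshold metrics plus AUC/AUPR for one score vector."""
    y = np.asarray(y).ravel().astype(int)
    scores = np.asarray(scores, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.size != scores.size:
        raise ValueError("y and scores must have equal length")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())

    acc = (tp + tn) / y.size
    pre = tp / (tp + fp) if tp + fp else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    both_classes = len(np.unique(y)) == 2
    return MetricsReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        acc=acc, pre=pre, sen=sen, spe=spe, mcc=mcc, f1=f1,
        auc=roc_auc(y, scores) if both_classes else float("nan"),
        aupr=pr_auc(y, scores) if both_classes else float("nan"),
        threshold=threshold,
    )


def _mean_report(reports: list[MetricsReport]) -> dict:
    keys = ["acc", "pre", "sen", "spe", "mcc", "f1", "auc", "aupr"]
    return {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}


def run_protocol(
    samples: PairFeatureSet,
    config: PipelineConfig,
    n_folds: int = 4,
    test_ratio_train: float = 0.8,
) -> dict:
    """8:2 split, stratified 4-fold CV on the training part, one test-set fit.

    Returns per-fold reports, their mean row and the held-out test report
    (mirroring the usual fold / mean / test table layout), plus the fitted
    full-training pipeline for reuse.
    """
    train, test = split_train_test(samples, ratio=test_ratio_train, seed=config.seed)
    folds = kfold_partition(train, k=n_folds, seed=config.seed)
    cv_reports: list[MetricsReport] = []
    for f, test_idx in enumerate(folds):
        mask = np.ones(train.n, dtype=bool)
        mask[test_idx] = False
        tr, te = train.subset(np.flatnonzero(mask)), train.subset(test_idx)
        fitted = fit_pipeline(tr.X, tr.y, config, seed_offset=f + 1)
        scores = pipeline_scores(fitted, te.X)
        cv_reports.append(confusion_metrics(te.y, scores))
    full = fit_pipeline(train.X, train.y, config)
    test_scores = pipeline_scores(full, test.X)
    test_report = confusion_metrics(test.y, test_scores)
    return {
        "cv_reports": cv_reports,
        "cv_mean": _mean_report(cv_reports),
        "test_report": test_report,
        "fitted": full,
        "train": train,
        "test": test,
    }


@dataclass
class RankedPredictions:
    """Top-ranked candidate miRNAs for one held-out disease."""

    disease_id: str
    rows: list[tuple[int, str, float]]  # (rank, mirna_id, score)
    masked_known: list[str] = field(default_factory=list)


def case_study(
    disease_id: str,
    assoc: AssociationMatrix,
    config: PipelineConfig,
    onto: DiseaseOntology | None = None,
    mfs: SimilarityMatrix | None = None,
    top_k: int = 50,
    reuse_global_similarity: bool = False,
) -> RankedPredictions:
    """Leave-one-disease-out ranking of candidate miRNAs.

    The held-out disease's column is zeroed and its pairs dropped from the
    labeled pool; GIP kernels (and hence MS, DS and all features) are
    recomputed from the masked matrix, the pipeline is retrained on the
    re-balanced sample, and all nm candidate pairs of the held-out disease
    are scored.  Ties are broken by miRNA id.

    ``reuse_global_similarity=True`` reproduces the laxer protocol that
    computes MS/DS once from the unmasked network: the held-out disease
    then keeps its (label-derived) GIP profile, which leaks association
    information into its own ranking.  The strict default removes every
    trace of the held-out column.
    """
    j = assoc.disease_ids.index(disease_id)
    masked_known = [assoc.mirna_ids[i] for i in np.flatnonzero(assoc.A[:, j])]
    masked = assoc.copy()
    masked.A[:, j] = 0
    if masked.n_associations == 0:
        raise ValueError("no other disease has known associations to train on")

    sim_source = assoc if reuse_global_similarity else masked
    ms, ds = integrated_similarities(sim_source, onto=onto, mfs=mfs)
    pairs = balanced_pair_sample(masked, seed=config.seed, exclude_diseases={j})
    feats = build_pair_features(ms, ds, masked, pairs, mask_target=True)
    fitted = fit_pipeline(feats.X, feats.y, config)

    candidates = [(i, j) for i in range(assoc.nm)]
    cand_feats = build_pair_features(ms, ds, masked, candidates, mask_target=True)
    scores = pipeline_scores(fitted, cand_feats.X)
    order = sorted(range(assoc.nm), key=lambda i: (-scores[i], assoc.mirna_ids[i]))
    rows = [
        (rank + 1, assoc.mirna_ids[i], float(scores[i]))
        for rank, i in enumerate(order[:top_k])
    ]
    return RankedPredictions(disease_id=disease_id, rows=rows, masked_known=masked_known)
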