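"""Performance assessment.

Six measures summarise a binary pathogenicity classifier: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total, positive and
negative predictive values TP/(TP+FP) and TN/(TN+FN), and the Matthews
correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).

TP/FN count correctly/incorrectly identified pathogenic variants, TN/FP
correctly/incorrectly identified neutral ones.  A ratio with a zero
denominator is reported as undefined (None), never coerced to 0.

Cross-validated estimates follow the original protocol: 10 replicas of a
stratified 5-fold split, SMOTE applied to the four training folds only,
replica metrics from pooled test-fold confusion counts, and the final
figure the mean over replicas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io_formats import MISSING, VariantRecord
from .learn import (
    SpecificModel,
    TrainingConfig,
    build_feature_matrix,
    smote_oversample,
    train_specific_model,
)
from .partition import PartitionResult, PredictorSpec, binarize

__all__ = [
    "MetricsReport",
    "CvPlan",
    "compute_metrics",
    "cross_validate",
    "evaluate_coincidence_rule",
    "evaluate_reference_predictor",
    "evaluate_hybrid",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Confusion counts, the six derived measures, and coverage.

    Undefined ratios (zero denominator) are None.  ``coverage`` is the
    fraction of the initial variant set that received a prediction.
    """

    TP: float
    TN: float
    FP: float
    FN: float
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    ppv: float | None = None
    npv: float | None = None
    mcc: float | None = None
    coverage: float | None = None

    @property
    def total(self) -> float:
        return self.TP + self.TN + self.FP + self.FN

    def as_dict(self) -> dict:
        return {
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "mcc": self.mcc,
            "coverage": self.coverage,
        }


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(
    TP: float, TN: float, FP: float, FN: float, coverage: float | None = None
) -> MetricsReport:
    """Derive the six performance measures from confusion counts."""
    for name, c in (("TP", TP), ("TN", TN), ("FP", FP), ("FN", FN)):
        if c < 0:
            raise ValueError(f"{name} must be non-negative")
    total = TP + TN + FP + FN
    if total == 0:
        raise ValueError("empty confusion table")
    denom = (TP + FN) * (TN + FP) * (TP + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / math.sqrt(denom) if denom > 0 else None
    return MetricsReport(
        TP=TP,
        TN=TN,
        FP=FP,
        FN=FN,
        sensitivity=_ratio(TP, TP + FN),
        specificity=_ratio(TN, TN + FP),
        accuracy=(TP + TN) / total,
        ppv=_ratio(TP, TP + FP),
        npv=_ratio(TN, TN + FN),
        mcc=mcc,
        coverage=coverage,
    )


def confusion_counts(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with 1 = pathogenic as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    TP = int(((y_true == 1) & (y_pred == 1)).sum())
    TN = int(((y_true == 0) & (y_pred == 0)).sum())
    FP = int(((y_true == 0) & (y_pred == 1)).sum())
    FN = int(((y_true == 1) & (y_pred == 0)).sum())
    return TP, TN, FP, FN


@dataclass
class CvPlan:
    """Replicated stratified k-fold layout (defaults: 10 x 5-fold)."""

    n_folds: int = 5
    n_replicas: int = 10
    stratified: bool = True
    seeds: list = field(default_factory=lambda: list(range(10)))

    def __post_init__(self):
        if len(self.seeds) != self.n_replicas:
            raise ValueError("need one seed per replica")


def cross_validate(
    records: Sequence[VariantRecord],
    combination: Sequence[str],
    config: TrainingConfig | None = None,
    plan: CvPlan | None = None,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Replicated stratified k-fold estimate for a specific predictor.

    Per replica: the PRDIS set is split into stratified folds; for each
    fold the remaining folds are SMOTE-balanced and fitted, the held-out
    fold is scored untouched, and confusion counts are pooled over folds.
    The averaged report takes the mean of each defined measure across
    replicas (replicas where a measure is undefined are excluded from
    that mean, with a logged count).
    """
    config = config or TrainingConfig()
    plan = plan or CvPlan()
    X, y, names = build_feature_matrix(records, combination, config.feature_set)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")
    replica_reports: list[MetricsReport] = []
    for seed in plan.seeds:
        splitter = StratifiedKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=seed
        )
        TP = TN = FP = FN = 0
        for train_idx, test_idx in splitter.split(X, y):
            X_tr, y_tr = X[train_idx], y[train_idx]
            X_te, y_te = X[test_idx], y[test_idx]
            X_bal, y_bal = smote_oversample(
                X_tr, y_tr, k=config.smote_k, seed=seed
            )
            model = train_specific_model(
                X_bal,
                y_bal,
                config,
                combination=combination,
                feature_names=names,
            )
            scores = model.predict_scores(X_te)
            y_hat = (scores >= config.decision_threshold).astype(int)
            tp, tn, fp, fn = confusion_counts(y_te, y_hat)
            TP += tp
            TN += tn
            FP += fp
            FN += fn
        replica_reports.append(compute_metrics(TP, TN, FP, FN, coverage=1.0))
    mean_report = _mean_reports(replica_reports)
    return mean_report, replica_reports


def _mean_reports(reports: Sequence[MetricsReport]) -> MetricsReport:
    def mean_of(attr):
        vals = [getattr(r, attr) for r in reports]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            logger.info(
                "%s undefined in %d/%d replicas; excluded from the mean",
                attr, len(vals) - len(defined), len(vals),
            )
        return float(np.mean(defined)) if defined else None

    return MetricsReport(
        TP=float(np.mean([r.TP for r in reports])),
        TN=float(np.mean([r.TN for r in reports])),
        FP=float(np.mean([r.FP for r in reports])),
        FN=float(np.mean([r.FN for r in reports])),
        sensitivity=mean_of("sensitivity"),
        specificity=mean_of("specificity"),
        accuracy=mean_of("accuracy"),
        ppv=mean_of("ppv"),
        npv=mean_of("npv"),
        mcc=mean_of("mcc"),
        coverage=mean_of("coverage"),
    )


def _true_binary(rec: VariantRecord) -> int:
    if rec.label == "pathogenic":
        return 1
    if rec.label == "neutral":
        return 0
    raise ValueError(f"{rec.replacement}: unlabeled record in evaluation")


def evaluate_coincidence_rule(
    records: Sequence[VariantRecord], partition: PartitionResult
) -> MetricsReport:
    """Score the unanimous calls against the labels.

    Metrics are computed on AGREE members only; coverage is
    |AGREE| / initial count, reflecting how much of the variant set the
    rule actually annotates.
    """
    TP = TN = FP = FN = 0
    for idx, call in partition.agree.items():
        truth = _true_binary(records[idx])
        pred = 1 if call == "pathogenic" else 0
        if truth == 1 and pred == 1:
            TP += 1
        elif truth == 0 and pred == 0:
            TN += 1
        elif truth == 0:
            FP += 1
        else:
            FN += 1
    coverage = len(partition.agree) / len(records) if records else 0.0
    if TP + TN + FP + FN == 0:
        return MetricsReport(0, 0, 0, 0, coverage=coverage)
    return compute_metrics(TP, TN, FP, FN, coverage=coverage)


def evaluate_reference_predictor(
    records: Sequence[VariantRecord], spec: PredictorSpec
) -> MetricsReport:
    """Individual performance of one reference tool.

    Metrics cover every labelled record for which the tool produced an
    output; coverage is reported against the full initial set.
    """
    TP = TN = FP = FN = 0
    n_output = 0
    for rec in records:
        call = binarize(rec, spec)
        if call is MISSING:
            continue
        n_output += 1
        truth = _true_binary(rec)
        pred = 1 if call == "pathogenic" else 0
        if truth == 1 and pred == 1:
            TP += 1
        elif truth == 0 and pred == 0:
            TN += 1
        elif truth == 0:
            FP += 1
        else:
            FN += 1
    coverage = n_output / len(records) if records else 0.0
    if n_output == 0:
        return MetricsReport(0, 0, 0, 0, coverage=0.0)
    return compute_metrics(TP, TN, FP, FN, coverage=coverage)


def evaluate_hybrid(
    records: Sequence[VariantRecord],
    partition: PartitionResult,
    model: SpecificModel,
) -> MetricsReport:
    """Score the hybrid predictor: unanimous call where the tools agree,
    the specific model's call on the PRDIS subset.

    Confusion counts from the two parts are pooled; NO-OUTPUT variants
    receive no prediction and enter only the coverage denominator.  The
    model must have been trained on variants disjoint from those scored
    here (or be assessed through cross-validation folds).
    """
    if tuple(model.combination) != tuple(partition.combination):
        raise ValueError(
            f"model combination {model.combination} does not match "
            f"partition combination {partition.combination}"
        )
    agree_part = evaluate_coincidence_rule(records, partition)
    TP, TN, FP, FN = agree_part.TP, agree_part.TN, agree_part.FP, agree_part.FN
    prdis_idx = sorted(partition.prdis)
    if prdis_idx:
        prdis_records = [records[i] for i in prdis_idx]
        _, calls = model.predict_records(prdis_records)
        y_true = [_true_binary(r) for r in prdis_records]
        y_pred = [1 if c == "pathogenic" else 0 for c in calls]
        tp, tn, fp, fn = confusion_counts(y_true, y_pred)
        TP += tp
        TN += tn
        FP += fp
        FN += fn
    coverage = (
        (len(partition.agree) + len(partition.prdis)) / len(records)
        if records
        else 0.0
    )
    if TP + TN + FP + FN == 0:
        return MetricsReport(0, 0, 0, 0, coverage=coverage)
    return compute_metrics(TP, TN, FP, FN, coverage=coverage)
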