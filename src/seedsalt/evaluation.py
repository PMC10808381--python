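"""Prediction evaluation: confusion counts, five metrics, Fisher's exact
test, and plate-level k-fold cross-validation.

The positive class is salt.  The five metrics are

    accuracy    = (TP + TN) / total
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Ratios with a zero denominator are reported as absent (None), never as 0.
Fisher's exact test is two-sided, computed by exhaustive hypergeometric
enumeration at fixed margins: p is the sum of the probabilities of all
tables no more probable than the observed one (with 1e-7 relative slack on
the comparison).  k-fold cross-validation splits at the plate level,
stratified by condition, trains the consensus ensemble on the remaining
plates and pools the confusion counts over folds before computing metrics
once (micro-averaging).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import exp, lgamma
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .ensemble import (NON_SALT, SALT, TrainingError, classify_plate,
                       predict_seeds, train_ensemble)
from .features import SeedRecord
from .io_config import InputError

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def scaled(self, factor: int) -> "ConfusionCounts":
        return ConfusionCounts(self.tp * factor, self.tn * factor,
                               self.fp * factor, self.fn * factor)


@dataclass
class MetricsReport:
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    fisher_p: Optional[float] = None


@dataclass
class KFoldConfig:
    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InputError("k must be >= 2")


def confusion_counts(predicted: Sequence[str], reference: Sequence[str]) -> ConfusionCounts:
    """Tally a 2x2 confusion table of salt/non-salt status calls."""
    if len(predicted) != len(reference):
        raise InputError(f"length mismatch: {len(predicted)} predictions vs "
                         f"{len(reference)} references")
    if len(predicted) == 0:
        raise InputError("need at least one prediction")
    c = ConfusionCounts(0, 0, 0, 0)
    for pred, ref in zip(predicted, reference):
        if ref == SALT:
            if pred == SALT:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if pred == SALT:
                c.fp += 1
            else:
                c.tn += 1
    return c


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def performance_metrics(c: ConfusionCounts) -> MetricsReport:
    """The five benchmark metrics; undefined ratios are absent, not 0."""
    if c.total < 1:
        raise InputError("confusion table is empty")
    sens = _ratio(c.tp, c.tp + c.fn)
    prec = _ratio(c.tp, c.tp + c.fp)
    f1 = None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=sens,
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=prec,
        f1=f1,
    )


def _lchoose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact(c: ConfusionCounts) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[tp, fn], [fp, tn]].

    Enumerates the full hypergeometric support at the observed margins and
    sums the probabilities of tables whose probability does not exceed the
    observed table's (relative slack 1e-7).  Degenerate margins give p = 1.
    """
    r1, r2 = c.tp + c.fn, c.fp + c.tn
    c1, c2 = c.tp + c.fp, c.fn + c.tn
    n = c.total
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = np.array([_lchoose(r1, k) + _lchoose(r2, c1 - k) for k in ks]) - _lchoose(n, c1)
    probs = np.exp(logp)
    p_obs = exp(_lchoose(r1, c.tp) + _lchoose(r2, c.fp) - _lchoose(n, c1))
    p = probs[probs <= p_obs * (1.0 + 1e-7)].sum()
    return float(min(p, 1.0))


def evaluate(predicted: Sequence[str], reference: Sequence[str]) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts plus the five metrics and Fisher's exact p."""
    counts = confusion_counts(predicted, reference)
    report = performance_metrics(counts)
    report.fisher_p = fisher_exact(counts)
    return counts, report


def _group_plates(records: Sequence[SeedRecord]) -> tuple[list[str], dict[str, list[SeedRecord]], dict[str, str]]:
    by_plate: dict[str, list[SeedRecord]] = {}
    for r in records:
        by_plate.setdefault(r.plate, []).append(r)
    conditions = {}
    for plate, recs in by_plate.items():
        labels = {r.condition for r in recs}
        if len(labels) != 1 or None in labels:
            raise InputError(f"plate {plate!r} must carry exactly one condition label")
        conditions[plate] = labels.pop()
    return list(by_plate), by_plate, conditions


def run_kfold(records: Sequence[SeedRecord], subset: str = "all",
              cfg: KFoldConfig = KFoldConfig()) -> tuple[ConfusionCounts, MetricsReport]:
    """Plate-level k-fold cross-validation of the consensus classifier.

    Plates are shuffled and split into k folds (stratified by condition by
    default); each fold is classified by an ensemble trained on the other
    folds.  Confusion counts are pooled over folds, then the metrics and
    Fisher's p are computed once.  A training fold that loses one of the
    two classes is skipped with a warning.
    """
    plates, by_plate, conditions = _group_plates(records)
    if cfg.k > len(plates):
        raise InputError(f"k={cfg.k} exceeds the number of plates ({len(plates)})")
    y = np.array([conditions[p] for p in plates])
    min_class = min(np.bincount(np.unique(y, return_inverse=True)[1]))
    if cfg.stratified and cfg.k <= min_class:
        splitter = StratifiedKFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
    else:
        if cfg.stratified:
            logger.info("k=%d exceeds the smallest class (%d plates); "
                        "using unstratified folds", cfg.k, min_class)
        splitter = KFold(n_splits=cfg.k, shuffle=True, random_state=cfg.seed)
    predicted: list[str] = []
    reference: list[str] = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(plates)), y)):
        train_records = [r for i in train_idx for r in by_plate[plates[i]]]
        try:
            model = train_ensemble(train_records, subset=subset, seed=cfg.seed)
        except TrainingError as exc:
            logger.warning("skipping fold %d: %s", fold, exc)
            continue
        for i in test_idx:
            plate = plates[i]
            pred = classify_plate(plate, predict_seeds(model, by_plate[plate]))
            predicted.append(pred.status)
            reference.append(conditions[plate])
    counts = confusion_counts(predicted, reference)
    report = performance_metrics(counts)
    report.fisher_p = fisher_exact(counts)
    return counts, report


def display_rounded(x: float, digits: int = 2) -> float:
    """Half-up rounding at ``digits`` decimals."""
    q = 10**digits
    return np.floor(x * q + 0.5) / q


def display_truncated(x: float, digits: int = 2) -> float:
    """Truncation toward zero at ``digits`` decimals."""
    q = 10**digits
    return np.trunc(x * q) / q
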