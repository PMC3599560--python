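"""Confusion matrices, MCC and repeated stratified k-fold cross-validation.

The Matthews Correlation Coefficient is the selected accuracy metric:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

ranging from -1 (total disagreement) to 1 (perfect agreement), with the
standard convention that a zero factor in the denominator yields 0.
Class 1 is the positive class.

Cross-validation is stratified (per-class counts across folds differ by
at most one) and repeated: each repeat r draws its folds from
``seed + r``, trains on k-1 folds — the learner refits gene filtering
and every internal selection inside the fold — predicts the held-out
fold, and pools one confusion matrix per repeat.  The summary is the
mean and standard deviation of the per-repeat MCC and accuracy over the
repeats.  Defaults: 10 folds, 10 repeats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .datamodel import CLASS_1, CLASS_2, DataError, ExpressionDataset, Learner

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """2x2 counts with class 1 as positive."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def add(self, truth: int, prediction: int) -> None:
        if truth == CLASS_1:
            if prediction == CLASS_1:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if prediction == CLASS_2:
                self.tn += 1
            else:
                self.fp += 1

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def mcc(confusion: ConfusionMatrix) -> float:
    """Matthews Correlation Coefficient; zero-denominator convention -> 0."""
    c = confusion
    if c.total < 1:
        raise DataError("confusion matrix is empty")
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


@dataclass
class RunResult:
    """One repeat of cross-validation."""

    seed: int
    confusion: ConfusionMatrix
    accuracy: float
    mcc: float


@dataclass
class EvaluationResult:
    per_run: list[RunResult] = field(default_factory=list)
    mean_mcc: float = 0.0
    sd_mcc: float = 0.0
    mean_accuracy: float = 0.0
    sd_accuracy: float = 0.0

    def to_dict(self) -> dict:
        return {
            "mean_mcc": self.mean_mcc,
            "sd_mcc": self.sd_mcc,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "runs": [
                {
                    "seed": r.seed,
                    "tp": r.confusion.tp,
                    "fp": r.confusion.fp,
                    "tn": r.confusion.tn,
                    "fn": r.confusion.fn,
                    "accuracy": r.accuracy,
                    "mcc": r.mcc,
                }
                for r in self.per_run
            ],
        }


def stratified_folds(dataset: ExpressionDataset, k: int, seed: int) -> list[list[str]]:
    """Partition the labelled samples into k class-balanced folds.

    Each class's samples are shuffled with the seed and dealt
    round-robin, so per-class counts across folds differ by at most
    one.  If a class has fewer than k samples, k is lowered to the
    minimum class size (logged); a class with fewer than 2 samples is
    an error.
    """
    if k < 2:
        raise DataError("k must be >= 2")
    n1, n2 = dataset.class_sizes()
    if min(n1, n2) < 2:
        raise DataError(f"each class needs >= 2 samples (have {n1}/{n2})")
    k_eff = min(k, n1, n2)
    if k_eff < k:
        logger.warning("lowering folds from %d to %d (min class size)", k, k_eff)
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k_eff)]
    for label in (CLASS_1, CLASS_2):
        ids = dataset.class_sample_ids(label)
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            folds[pos % k_eff].append(ids[idx])
    return folds


def cross_validate(
    dataset: ExpressionDataset,
    learner: Learner,
    params: Mapping | None = None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated stratified k-fold CV with per-repeat pooled confusion.

    Gene filtering and all model selection happen inside ``learner.train``
    on the fold's training samples only.  With ``repeats == 1`` the
    standard deviations are 0 by convention.
    """
    dataset.require_two_classes()
    labeled = dataset.subset_samples(dataset.labeled_sample_ids())
    result = EvaluationResult()
    for r in range(repeats):
        fold_seed = seed + r
        folds = stratified_folds(labeled, k, fold_seed)
        confusion = ConfusionMatrix()
        for fold in folds:
            held_out = set(fold)
            train_ids = [s for s in labeled.sample_ids if s not in held_out]
            train_ds = labeled.subset_samples(train_ids)
            try:
                model = learner.train(train_ds, params)
            except Exception as e:
                raise type(e)(f"{e} (repeat {r}, fold with {sorted(held_out)})") from e
            for sid in fold:
                pred = learner.classify(model, labeled.sample_vector(sid))
                confusion.add(labeled.class_of[sid], pred)
        result.per_run.append(
            RunResult(fold_seed, confusion, confusion.accuracy, mcc(confusion))
        )
    mccs = [r.mcc for r in result.per_run]
    accs = [r.accuracy for r in result.per_run]
    result.mean_mcc = float(np.mean(mccs))
    result.mean_accuracy = float(np.mean(accs))
    if repeats > 1:
        result.sd_mcc = float(np.std(mccs, ddof=1))
        result.sd_accuracy = float(np.std(accs, ddof=1))
    return result
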