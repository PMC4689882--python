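"""Recall / Precision / F evaluation and cross-validated method comparison.

Recall = TP/(TP+FN), Precision = TP/(TP+FP), F = 2RP/(R+P); a zero
denominator yields 0 with the ``degenerate`` flag set. The outer k-fold
cross-validation is stratified by gold label; DK refinement and all model
fitting run strictly inside the training side of each fold, and per-fold
counts are pooled (micro-averaged) for the headline numbers with macro
averages reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import subset_models
from .corpus_io import Instance, POSITIVE
from .dominant_keyword import DKConfig, LearnerFactory, _fold_indices


@dataclass
class EvalResult:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    recall: float = 0.0
    precision: float = 0.0
    f_value: float = 0.0
    degenerate: bool = False
    per_fold: list["EvalResult"] = field(default_factory=list)
    macro_recall: Optional[float] = None
    macro_precision: Optional[float] = None
    macro_f: Optional[float] = None


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(recall, precision, F); zero-denominator terms evaluate to 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f = (2 * recall * precision / (recall + precision)
         if recall + precision else 0.0)
    return recall, precision, f


def _result_from_counts(tp: int, fp: int, fn: int, tn: int) -> EvalResult:
    recall, precision, f = prf(tp, fp, fn)
    degenerate = (tp + fn == 0) or (tp + fp == 0) or (recall + precision == 0)
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn, recall=recall,
                      precision=precision, f_value=f, degenerate=degenerate)


def score_predictions(instances: Sequence[Instance],
                      predictions: Sequence[str]) -> EvalResult:
    tp = fp = fn = tn = 0
    for inst, pred in zip(instances, predictions):
        gold_pos = inst.label == POSITIVE
        pred_pos = pred == POSITIVE
        if gold_pos and pred_pos:
            tp += 1
        elif gold_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return _result_from_counts(tp, fp, fn, tn)


def cross_validate(method: str, instances: Sequence[Instance], k: int = 10,
                   config: Optional[DKConfig] = None,
                   learner: Optional[LearnerFactory] = None) -> EvalResult:
    """Outer stratified k-fold CV of one method variant.

    Instances must carry extracted features. Fold assignment uses the
    configured seed, so method comparisons on the same config share folds.
    """
    instances = list(instances)
    if k > len(instances):
        raise ValueError(f"k={k} exceeds the {len(instances)} instances")
    config = config or DKConfig()
    y = np.array([1 if i.label == POSITIVE else 0 for i in instances])
    folds = _fold_indices(y, k, config.rng_seed)
    per_fold: list[EvalResult] = []
    for fold in folds:
        test_ids = {instances[i].id for i in fold}
        train = [i for i in instances if i.id not in test_ids]
        test = [instances[i] for i in fold]
        assert not ({t.id for t in train} & test_ids), "train/test leakage"
        bundle = subset_models.fit(method, train, config=config,
                                   learner=learner)
        preds = subset_models.predict(bundle, test)
        per_fold.append(score_predictions(test, preds))
    total = _result_from_counts(
        tp=sum(r.tp for r in per_fold), fp=sum(r.fp for r in per_fold),
        fn=sum(r.fn for r in per_fold), tn=sum(r.tn for r in per_fold))
    total.per_fold = per_fold
    total.macro_recall = float(np.mean([r.recall for r in per_fold]))
    total.macro_precision = float(np.mean([r.precision for r in per_fold]))
    total.macro_f = float(np.mean([r.f_value for r in per_fold]))
    return total


def compare_methods(instances: Sequence[Instance],
                    methods: Sequence[str] = subset_models.METHODS,
                    k: int = 10,
                    config: Optional[DKConfig] = None,
                    learner: Optional[LearnerFactory] = None) -> pd.DataFrame:
    """Cross-validate several methods on identical folds; one row per method
    with micro-averaged R, P and F (percent)."""
    rows = []
    for method in methods:
        res = cross_validate(method, instances, k=k, config=config,
                             learner=learner)
        rows.append({"method": method,
                     "R": 100 * res.recall,
                     "P": 100 * res.precision,
                     "F": 100 * res.f_value})
    return pd.DataFrame(rows).set_index("method")
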