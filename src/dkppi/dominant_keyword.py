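"""Per-instance dominant-keyword (DK) prediction.

A keyword is *dominant* for an instance when it is the decisive evidence for
the class label. The unbalance degree of a keyword K,

    U(K) = (# positive instances whose selected keyword is K)
           / (# instances whose selected keyword is K),

seeds the initial assumption: every instance whose keyword satisfies
min(U, 1-U) < T starts with DK = 1, all others with DK = 0. The assumption
is then refined over m rounds of k-fold cross-validation: two classifiers
C0 (trained on DK=0 instances) and C1 (trained on DK=1 instances) predict
each held-out instance, and

* Case 1 — the two predictions differ: DK follows the correct classifier;
* Case 2 — both correct: a true-negative instance flips its DK with the
  mutation rate alpha (escape from local stable states);
* Case 3 — both wrong: a gold-negative instance is removed from training.

Finally the DK-classifier is trained with the refined DK values as labels so
unlabeled instances can be assigned a DK value at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .corpus_io import Instance, POSITIVE
from .features import FeatureEncoder

logger = logging.getLogger(__name__)

LearnerFactory = Callable[[], object]


@dataclass
class DKConfig:
    threshold_T: float = 0.15
    folds_k: int = 10
    iterations_m: int = 5
    mutation_alpha: float = 0.05
    rng_seed: int = 0
    #: re-draw the CV partition at every iteration (vs. reuse one partition)
    repartition_each_iteration: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold_T <= 0.5:
            raise ValueError("threshold_T must lie in (0, 0.5]")
        if self.folds_k < 2 or self.iterations_m < 0:
            raise ValueError("folds_k >= 2 and iterations_m >= 0 required")
        if not 0 <= self.mutation_alpha <= 1:
            raise ValueError("mutation_alpha must be a probability")


@dataclass
class DKState:
    dk: dict[str, int] = field(default_factory=dict)
    removed: set[str] = field(default_factory=set)
    history: list[dict] = field(default_factory=list)

    def survivors(self, instances: Sequence[Instance]) -> list[Instance]:
        return [i for i in instances if i.id not in self.removed]

    def apply(self, instances: Iterable[Instance]) -> None:
        """Copy DK values onto the instances."""
        for inst in instances:
            inst.dk = self.dk.get(inst.id)


def default_learner(seed: int = 0, n_estimators: int = 100) -> LearnerFactory:
    """Random-forest learner factory (the package's default classifier)."""

    def factory() -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1)

    return factory


class MajorityClassifier:
    """Degraded stand-in used when a training side is empty or single-class."""

    def __init__(self, label: int):
        self.label = int(label)

    def fit(self, X, y):  # noqa: D102 - sklearn-style no-op
        return self

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


def _y(instances: Sequence[Instance]) -> np.ndarray:
    return np.array([1 if i.label == POSITIVE else 0 for i in instances])


def unbalance_degree(keyword_stem: str,
                     instances: Sequence[Instance]) -> float:
    """U(K): fraction of positives among instances whose keyword is K."""
    with_k = [i for i in instances
              if i.keyword is not None and i.keyword.stem == keyword_stem]
    if not with_k:
        raise ValueError(f"no instance has selected keyword {keyword_stem!r}")
    return sum(i.label == POSITIVE for i in with_k) / len(with_k)


def dominant_stems(instances: Sequence[Instance], threshold_T: float) -> set[str]:
    """Keyword stems whose unbalance degree clears the threshold (strict <)."""
    counts: dict[str, list[int]] = {}
    for i in instances:
        if i.keyword is None:
            continue
        pos, tot = counts.setdefault(i.keyword.stem, [0, 0])
        counts[i.keyword.stem][0] += i.label == POSITIVE
        counts[i.keyword.stem][1] += 1
    out = set()
    for stem, (pos, tot) in counts.items():
        u = pos / tot
        if min(u, 1.0 - u) < threshold_T:
            out.add(stem)
    return out


def initial_dk(instances: Sequence[Instance], config: DKConfig) -> DKState:
    """DK = 1 iff the instance's keyword is initially assumed dominant."""
    dom = dominant_stems(instances, config.threshold_T)
    dk = {i.id: int(i.keyword is not None and i.keyword.stem in dom)
          for i in instances}
    return DKState(dk=dk)


def _fit_side(X: np.ndarray, y: np.ndarray, fallback: int,
              learner: LearnerFactory):
    if len(y) == 0 or len(np.unique(y)) < 2:
        logger.info("degenerate training side (n=%d): majority stub", len(y))
        return MajorityClassifier(fallback)
    est = learner()
    est.fit(X, y)
    return est


def train_c0_c1(train_instances: Sequence[Instance], dkstate: DKState,
                learner: LearnerFactory, encoder: FeatureEncoder):
    """Fit C0 on the DK=0 side and C1 on the DK=1 side (all 44 features)."""
    insts = dkstate.survivors(train_instances)
    X = encoder.transform([i.features for i in insts])
    y = _y(insts)
    majority = int(np.round(y.mean())) if len(y) else 0
    side = np.array([dkstate.dk[i.id] for i in insts])
    c0 = _fit_side(X[side == 0], y[side == 0], majority, learner)
    c1 = _fit_side(X[side == 1], y[side == 1], majority, learner)
    return c0, c1


def update_dk_fold(fold_instances: Sequence[Instance], c0, c1,
                   dkstate: DKState, config: DKConfig,
                   rng: np.random.Generator,
                   encoder: FeatureEncoder) -> dict:
    """Apply the three update cases to one held-out fold (in place)."""
    insts = dkstate.survivors(fold_instances)
    if not insts:
        return {"case1": 0, "mutations": 0, "removed": 0}
    X = encoder.transform([i.features for i in insts])
    y = _y(insts)
    pred0 = np.asarray(c0.predict(X))
    pred1 = np.asarray(c1.predict(X))
    stats = {"case1": 0, "mutations": 0, "removed": 0}
    for inst, gold, p0, p1 in zip(insts, y, pred0, pred1):
        ok0, ok1 = p0 == gold, p1 == gold
        if ok0 != ok1:  # Case 1: predictions differ
            new = 1 if ok1 else 0
            if dkstate.dk[inst.id] != new:
                stats["case1"] += 1
            dkstate.dk[inst.id] = new
        elif ok0:  # Case 2: both correct
            if gold == 0 and rng.random() < config.mutation_alpha:
                dkstate.dk[inst.id] = 1 - dkstate.dk[inst.id]
                stats["mutations"] += 1
        else:  # Case 3: both incorrect
            if gold == 0:
                dkstate.removed.add(inst.id)
                del dkstate.dk[inst.id]
                stats["removed"] += 1
    return stats


def _fold_indices(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    n = len(y)
    k_eff = min(k, n)
    if k_eff < 2:
        return [np.arange(n)]
    class_min = int(np.bincount(y, minlength=2)[np.bincount(y, minlength=2) > 0].min())
    if class_min >= k_eff and len(np.unique(y)) == 2:
        splitter = StratifiedKFold(n_splits=k_eff, shuffle=True,
                                   random_state=seed)
    elif class_min >= 2 and len(np.unique(y)) == 2:
        splitter = StratifiedKFold(n_splits=class_min, shuffle=True,
                                   random_state=seed)
        logger.info("fold count reduced to %d (small class)", class_min)
    else:
        splitter = KFold(n_splits=k_eff, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(n), y)]


def refine_dk(instances: Sequence[Instance], config: DKConfig,
              learner: LearnerFactory,
              encoder: Optional[FeatureEncoder] = None) -> DKState:
    """Run the m-iteration, k-fold DK refinement loop over a training set."""
    instances = list(instances)
    if encoder is None:
        encoder = FeatureEncoder().fit([i.features for i in instances])
    state = initial_dk(instances, config)
    mutation_rng = np.random.default_rng(config.rng_seed + 7919)
    for it in range(config.iterations_m):
        survivors = state.survivors(instances)
        if not survivors:
            break
        fold_seed = (config.rng_seed + it if config.repartition_each_iteration
                     else config.rng_seed)
        folds = _fold_indices(_y(survivors), config.folds_k, fold_seed)
        stats = {"case1": 0, "mutations": 0, "removed": 0}
        for fold in folds:
            fold_ids = {survivors[i].id for i in fold}
            train = [i for i in survivors
                     if i.id not in fold_ids and i.id not in state.removed]
            fold_insts = [survivors[i] for i in fold
                          if survivors[i].id not in state.removed]
            if not train or not fold_insts:
                continue
            c0, c1 = train_c0_c1(train, state, learner, encoder)
            fstats = update_dk_fold(fold_insts, c0, c1, state, config,
                                    mutation_rng, encoder)
            for key in stats:
                stats[key] += fstats[key]
        state.history.append(stats)
    state.apply(state.survivors(instances))
    return state


@dataclass
class DKClassifier:
    """Predicts the DK value of unlabeled instances from their features."""

    encoder: FeatureEncoder
    estimator: object

    def predict(self, instances: Sequence[Instance]) -> list[int]:
        if not instances:
            return []
        X = self.encoder.transform([i.features for i in instances])
        return [int(v) for v in self.estimator.predict(X)]


def train_dk_classifier(instances: Sequence[Instance], dkstate: DKState,
                        learner: LearnerFactory,
                        encoder: FeatureEncoder) -> DKClassifier:
    """Fit the DK-classifier on survivors, DK values as class labels."""
    insts = dkstate.survivors(instances)
    X = encoder.transform([i.features for i in insts])
    y = np.array([dkstate.dk[i.id] for i in insts])
    if len(np.unique(y)) < 2:
        constant = int(y[0]) if len(y) else 0
        logger.info("all DK values identical: constant DK predictor (%d)",
                    constant)
        return DKClassifier(encoder, MajorityClassifier(constant))
    est = learner()
    est.fit(X, y)
    return DKClassifier(encoder, est)


def predict_dk(model: DKClassifier,
               unlabeled_instances: Sequence[Instance]) -> list[int]:
    values = model.predict(unlabeled_instances)
    for inst, v in zip(unlabeled_instances, values):
        inst.dk = v
    return values


def write_dk_state(state: DKState, path) -> None:
    """Serialize as CSV: instance_id,dk,removed."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("instance_id,dk,removed\n")
        for iid, dk in sorted(state.dk.items()):
            fh.write(f"{iid},{dk},0\n")
        for iid in sorted(state.removed):
            fh.write(f"{iid},,1\n")


def read_dk_state(path) -> DKState:
    state = DKState()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "instance_id,dk,removed":
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            iid, dk, removed = line.rstrip("\n").split(",")
            if removed == "1":
                state.removed.add(iid)
            else:
                state.dk[iid] = int(dk)
    return state
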