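"""Four-way training-set partition, per-subset feature masks, and the five
method configurations.

Crossing the per-instance DK value with the keyword position yields the four
subsets II (DK=1, infix), IP (DK=1, prefix/postfix), NI (DK=0, infix) and NP
(DK=0, prefix/postfix); an instance with no keyword routes to NP. One
classifier is trained per subset, and unlabeled instances are routed to the
classifier of their predicted subset.

Method variants:

* SC        — one classifier on the whole training set;
* MC        — DK from the unbalance-degree threshold alone (no refinement);
* DK-MC     — DK refined by the cross-validation loop + DK-classifier;
* FS-MC     — MC plus the per-subset feature masks;
* DK-FS-MC  — DK-MC plus the per-subset feature masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np

from .corpus_io import Instance, NEGATIVE, POSITIVE
from .dominant_keyword import (
    DKClassifier,
    DKConfig,
    DKState,
    LearnerFactory,
    MajorityClassifier,
    default_learner,
    dominant_stems,
    initial_dk,
    predict_dk,
    refine_dk,
    train_dk_classifier,
)
from .features import FeatureEncoder

SUBSETS = ("II", "IP", "NI", "NP")
METHODS = ("SC", "MC", "DK-MC", "FS-MC", "DK-FS-MC")

#: structure-pattern features removed per subset: the K-P1-P2-shaped patterns
#: are useless for infix (S-V-O) sentences, and vice versa.
_MASKS = {
    "II": ("pattern7", "pattern8", "pattern9", "pattern13"),
    "NI": ("pattern7", "pattern8", "pattern9", "pattern13"),
    "IP": ("pattern1", "pattern2", "pattern10", "pattern12"),
    "NP": ("pattern1", "pattern2", "pattern10", "pattern12"),
}


def assign_subset(dk_flag: int, position: str) -> str:
    """Route (DK value, keyword position) to one of the four subsets."""
    if position not in ("infix", "prefix", "postfix", "none"):
        raise ValueError(f"unknown keyword position {position!r}")
    if position == "none":
        return "NP"
    if dk_flag:
        return "II" if position == "infix" else "IP"
    return "NI" if position == "infix" else "NP"


def feature_mask(subset: str) -> tuple[str, ...]:
    """Names of the features removed for a subset's classifier."""
    return _MASKS[subset]


def _position_of(instance: Instance) -> str:
    f = instance.features
    if f.get("kw_infix"):
        return "infix"
    if f.get("kw_prefix"):
        return "prefix"
    if f.get("kw_postfix"):
        return "postfix"
    return "none"


@dataclass
class ModelBundle:
    method: str
    encoder: FeatureEncoder
    classifiers: dict[str, object]  # subset -> classifier; {"ALL": clf} for SC
    masks: dict[str, tuple[str, ...]] = field(default_factory=dict)
    dk_model: Optional[DKClassifier] = None
    dominant_stems: Optional[set[str]] = None
    dk_config: Optional[DKConfig] = None
    dk_state: Optional[DKState] = None


def fit(method: str, train_instances: Sequence[Instance],
        config: Optional[DKConfig] = None,
        learner: Optional[LearnerFactory] = None) -> ModelBundle:
    """Train a model bundle for one of the five method variants.

    Instances must carry extracted features (see features.extract_all).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    config = config or DKConfig()
    learner = learner or default_learner(config.rng_seed)
    train_instances = list(train_instances)
    encoder = FeatureEncoder().fit([i.features for i in train_instances])
    y_all = np.array([1 if i.label == POSITIVE else 0 for i in train_instances])
    majority = int(np.round(y_all.mean())) if len(y_all) else 0

    if method == "SC":
        X = encoder.transform([i.features for i in train_instances])
        clf = learner()
        clf.fit(X, y_all)
        return ModelBundle(method=method, encoder=encoder,
                           classifiers={"ALL": clf})

    use_masks = method in ("FS-MC", "DK-FS-MC")
    use_refinement = method in ("DK-MC", "DK-FS-MC")

    if use_refinement:
        state = refine_dk(train_instances, config, learner, encoder)
        dk_model = train_dk_classifier(train_instances, state, learner, encoder)
        doms = None
    else:
        state = initial_dk(train_instances, config)
        dk_model = None
        doms = dominant_stems(train_instances, config.threshold_T)

    survivors = state.survivors(train_instances)
    masks = {s: feature_mask(s) for s in SUBSETS} if use_masks else {}
    classifiers: dict[str, object] = {}
    for subset in SUBSETS:
        members = [i for i in survivors
                   if assign_subset(state.dk[i.id], _position_of(i)) == subset]
        mask = masks.get(subset, ())
        y = np.array([1 if i.label == POSITIVE else 0 for i in members])
        if len(members) == 0 or len(np.unique(y)) < 2:
            classifiers[subset] = MajorityClassifier(
                int(np.round(y.mean())) if len(y) else majority)
            continue
        X = encoder.transform([i.features for i in members], mask=mask)
        clf = learner()
        clf.fit(X, y)
        classifiers[subset] = clf

    return ModelBundle(method=method, encoder=encoder, classifiers=classifiers,
                       masks=masks, dk_model=dk_model, dominant_stems=doms,
                       dk_config=config, dk_state=state)


def _dk_at_prediction(bundle: ModelBundle,
                      instances: Sequence[Instance]) -> list[int]:
    if bundle.dk_model is not None:
        return predict_dk(bundle.dk_model, instances)
    doms = bundle.dominant_stems or set()
    return [int(i.keyword is not None and i.keyword.stem in doms)
            for i in instances]


def predict(bundle: ModelBundle,
            unlabeled_instances: Sequence[Instance]) -> list[str]:
    """Predict labels; instances must carry extracted features."""
    instances = list(unlabeled_instances)
    if not instances:
        return []
    if bundle.method == "SC":
        X = bundle.encoder.transform([i.features for i in instances])
        pred = bundle.classifiers["ALL"].predict(X)
        return [POSITIVE if p else NEGATIVE for p in pred]

    dks = _dk_at_prediction(bundle, instances)
    routes = [assign_subset(dk, _position_of(i))
              for dk, i in zip(dks, instances)]
    out = [""] * len(instances)
    for subset in SUBSETS:
        idx = [j for j, r in enumerate(routes) if r == subset]
        if not idx:
            continue
        mask = bundle.masks.get(subset, ())
        X = bundle.encoder.transform(
            [instances[j].features for j in idx], mask=mask)
        pred = bundle.classifiers[subset].predict(X)
        for j, p in zip(idx, pred):
            out[j] = POSITIVE if p else NEGATIVE
    return out


def save_bundle(bundle: ModelBundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "method": bundle.method,
        "masks": {k: list(v) for k, v in bundle.masks.items()},
        "dominant_stems": sorted(bundle.dominant_stems)
        if bundle.dominant_stems is not None else None,
        "subsets": sorted(bundle.classifiers),
        "dk_config": vars(bundle.dk_config) if bundle.dk_config else None,
    }
    (d / "bundle.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(bundle.encoder, d / "encoder.joblib")
    for name, clf in bundle.classifiers.items():
        joblib.dump(clf, d / f"classifier_{name}.joblib")
    if bundle.dk_model is not None:
        joblib.dump(bundle.dk_model, d / "dk_model.joblib")


def load_bundle(directory) -> ModelBundle:
    d = Path(directory)
    meta = json.loads((d / "bundle.json").read_text())
    encoder = joblib.load(d / "encoder.joblib")
    classifiers = {name: joblib.load(d / f"classifier_{name}.joblib")
                   for name in meta["subsets"]}
    dk_model = None
    if (d / "dk_model.joblib").exists():
        dk_model = joblib.load(d / "dk_model.joblib")
    doms = (set(meta["dominant_stems"])
            if meta["dominant_stems"] is not None else None)
    cfg = DKConfig(**meta["dk_config"]) if meta["dk_config"] else None
    return ModelBundle(method=meta["method"], encoder=encoder,
                       classifiers=classifiers,
                       masks={k: tuple(v) for k, v in meta["masks"].items()},
                       dk_model=dk_model, dominant_stems=doms, dk_config=cfg)
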