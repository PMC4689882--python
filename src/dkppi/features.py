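"""The 44-feature registry: extraction and numeric encoding.

The feature vector of an instance concatenates

* 25 lexical features (keyword, three word distances, the keyword-position
  indicator triple, two protein positions, comma pattern, five boolean flags,
  preposition, multiple-keyword flag, seven second-keyword flags, parallel
  expression),
* 6 parse features (three heights, three POS root paths),
* 13 structure-pattern flags.

Nominal features are encoded ordinally with a vocabulary learned from the
training split; values unseen at training time map to -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import linguistic_features as lf
from . import parse_features as pf
from . import pattern_features as patf
from .corpus_io import Instance
from .lexicon import SECOND_KEYWORD_WORDS, KeywordLexicon
from .stem import porter_stem

SECOND_KEYWORD_FEATURES = tuple(
    f"second_{w}" for w in SECOND_KEYWORD_WORDS)
PATTERN_FEATURES = tuple(f"pattern{i}" for i in range(1, 14))

FEATURE_NAMES: tuple[str, ...] = (
    "keyword",
    "dist_type1", "dist_type2", "dist_type3",
    "kw_infix", "kw_prefix", "kw_postfix",
    "position1", "position2",
    "comma",
    "negative", "conjunctive", "which", "but", "condition",
    "preposition",
    "multiple_keywords",
    *SECOND_KEYWORD_FEATURES,
    "parallel",
    "height_p1", "height_p2", "height_k",
    "pos_path_p1", "pos_path_p2", "pos_path_k",
    *PATTERN_FEATURES,
)

FEATURE_KINDS: dict[str, str] = {
    **{n: "bool" for n in FEATURE_NAMES},
    "keyword": "nominal", "comma": "nominal", "preposition": "nominal",
    "pos_path_p1": "nominal", "pos_path_p2": "nominal", "pos_path_k": "nominal",
    "dist_type1": "int", "dist_type2": "int", "dist_type3": "int",
    "position1": "int", "position2": "int",
    "height_p1": "int", "height_p2": "int", "height_k": "int",
}

NOMINAL_FEATURES = tuple(n for n in FEATURE_NAMES
                         if FEATURE_KINDS[n] == "nominal")


def extract_features(instance: Instance, lexicon: KeywordLexicon,
                     patterns: Optional[Sequence[patf.PatternSpec]] = None,
                     ) -> dict:
    """Compute all 44 features; stores them on the instance and returns them."""
    if patterns is None:
        patterns = patf.compile_patterns(lexicon)
    kw = lf.select_keyword(instance, lexicon)
    instance.keyword = kw

    d1, d2, d3 = lf.distance_features(instance, kw)
    position = lf.keyword_position(instance, kw)
    pos1, pos2 = lf.protein_positions(instance)
    neg, conj, which, but, cond = lf.boolean_flags(instance, kw, lexicon)
    multiple, second = lf.multiple_and_second_keywords(instance, kw, lexicon)
    h1, h2, hk = pf.height_features(instance.sentence.tree, instance, kw)
    pp1, pp2, ppk = pf.pos_paths(instance.sentence.tree, instance, kw)
    pvec = patf.pattern_vector(instance, patterns, lexicon)

    feats: dict = {
        "keyword": kw.stem if kw is not None else "none",
        "dist_type1": d1, "dist_type2": d2, "dist_type3": d3,
        "kw_infix": position == "infix",
        "kw_prefix": position == "prefix",
        "kw_postfix": position == "postfix",
        "position1": pos1, "position2": pos2,
        "comma": lf.comma_feature(instance, kw),
        "negative": neg, "conjunctive": conj, "which": which, "but": but,
        "condition": cond,
        "preposition": lf.preposition_of_keyword(instance, kw, lexicon),
        "multiple_keywords": multiple,
        "parallel": lf.parallel_expression(instance),
        "height_p1": h1, "height_p2": h2, "height_k": hk,
        "pos_path_p1": pp1, "pos_path_p2": pp2, "pos_path_k": ppk,
    }
    for word, name in zip(SECOND_KEYWORD_WORDS, SECOND_KEYWORD_FEATURES):
        feats[name] = second.get(porter_stem(word), False)
    for name, hit in zip(PATTERN_FEATURES, pvec):
        feats[name] = hit
    assert set(feats) == set(FEATURE_NAMES)
    instance.features = feats
    return feats


def extract_all(instances: Iterable[Instance], lexicon: KeywordLexicon) -> None:
    patterns = patf.compile_patterns(lexicon)
    for inst in instances:
        extract_features(inst, lexicon, patterns)


@dataclass
class FeatureEncoder:
    """Ordinal encoder from feature dicts to a dense numeric matrix."""

    feature_names: tuple[str, ...] = FEATURE_NAMES
    vocab_: dict[str, dict[str, int]] = field(default_factory=dict)

    def fit(self, feature_dicts: Iterable[dict]) -> "FeatureEncoder":
        dicts = list(feature_dicts)
        self.vocab_ = {}
        for name in self.feature_names:
            if FEATURE_KINDS[name] == "nominal":
                values = sorted({d[name] for d in dicts})
                self.vocab_[name] = {v: i for i, v in enumerate(values)}
        return self

    def transform(self, feature_dicts: Iterable[dict],
                  mask: Iterable[str] = ()) -> np.ndarray:
        """Encode; features named in `mask` are dropped from the matrix."""
        drop = set(mask)
        names = [n for n in self.feature_names if n not in drop]
        rows = []
        for d in feature_dicts:
            row = []
            for name in names:
                v = d[name]
                if FEATURE_KINDS[name] == "nominal":
                    row.append(self.vocab_[name].get(v, -1))
                else:
                    row.append(int(v))
            rows.append(row)
        return np.asarray(rows, dtype=np.float64).reshape(len(rows), len(names))

    def fit_transform(self, feature_dicts: Iterable[dict],
                      mask: Iterable[str] = ()) -> np.ndarray:
        dicts = list(feature_dicts)
        return self.fit(dicts).transform(dicts, mask)
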