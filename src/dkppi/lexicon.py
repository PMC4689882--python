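"""Keyword lexicon: stemmed interaction-trigger words and auxiliary word lists.

The lexicon drives keyword selection (the trigger word of an instance), the
iVerb/iNoun slots of the structure patterns, the seven "second keywords", and
the negation / conjunction / condition / preposition flag features.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .stem import porter_stem

#: The seven high-salience interaction words tracked individually even when
#: another keyword is selected for the instance.
SECOND_KEYWORD_WORDS = (
    "bind", "interact", "regulate", "induce", "stimulate", "associate", "known",
)

_SECTIONS = (
    "keywords", "iverb", "inoun", "second",
    "negative", "conjunctive", "condition", "prepositions",
)


@dataclass(frozen=True)
class KeywordLexicon:
    """Sets of Porter stems partitioned by role."""

    keywords: frozenset[str]
    iverb: frozenset[str]
    inoun: frozenset[str]
    second_keywords: tuple[str, ...]
    negatives: frozenset[str]
    conjunctives: frozenset[str]
    condition_words: frozenset[str]
    prepositions: frozenset[str]

    def __post_init__(self) -> None:
        if not set(self.second_keywords) <= self.keywords:
            raise ValueError("second keywords must be a subset of keywords")
        if not (self.iverb | self.inoun) <= self.keywords:
            raise ValueError("iVerb and iNoun must be subsets of keywords")

    def is_keyword(self, stem: str) -> bool:
        return stem in self.keywords


def _stems(words) -> frozenset[str]:
    return frozenset(porter_stem(w) for w in words)


def load_lexicon(path) -> KeywordLexicon:
    """Read a sectioned word-list file; entries are stemmed at load time."""
    sections: dict[str, list[str]] = {name: [] for name in _SECTIONS}
    current: str | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                if current not in sections:
                    raise ValueError(
                        f"{path}:{lineno}: unknown section [{current}]"
                    )
                continue
            if current is None:
                raise ValueError(f"{path}:{lineno}: entry before any section")
            sections[current].append(line.lower())

    second = tuple(dict.fromkeys(porter_stem(w) for w in sections["second"]))
    keywords = _stems(sections["keywords"]) | _stems(sections["iverb"]) \
        | _stems(sections["inoun"]) | frozenset(second)
    return KeywordLexicon(
        keywords=keywords,
        iverb=_stems(sections["iverb"]),
        inoun=_stems(sections["inoun"]),
        second_keywords=second,
        negatives=_stems(sections["negative"]),
        conjunctives=frozenset(w for w in sections["conjunctive"]),
        condition_words=frozenset(w for w in sections["condition"]),
        prepositions=frozenset(w for w in sections["prepositions"]),
    )


_default: KeywordLexicon | None = None


def default_lexicon() -> KeywordLexicon:
    """The lexicon shipped with the package (cached)."""
    global _default
    if _default is None:
        ref = importlib.resources.files("dkppi.data") / "default_lexicon.txt"
        with importlib.resources.as_file(ref) as path:
            _default = load_lexicon(path)
    return _default
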