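"""The thirteen PPI structure patterns, matched over blinded word tokens.

A pattern is an ordered element sequence over {literal word, P1, P2, iVerb,
iNoun, alternation, wildcard}. The wildcard matches zero to five word tokens;
literals and the iVerb/iNoun classes match by Porter stem; P1/P2 match the
blinded placeholder tokens. A pattern fires when its sequence matches any
contiguous run of word tokens in the blinded sentence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .corpus_io import Instance, Token, blind_proteins
from .lexicon import KeywordLexicon
from .stem import porter_stem

WILDCARD_LIMIT = 5

#: Table of the built-in pattern strings; grammar: `*` wildcard, `P1`/`P2`
#: protein slots, `iVerb`/`iNoun` class slots, `[a|b]` alternation, else a
#: stem-matched literal.
PATTERN_STRINGS: tuple[str, ...] = (
    "P1 * iVerb * P2",
    "P1 * iVerb * by * P2",
    "iVerb of * P1 * by * P2",
    "iVerb of * P1 * to * P2",
    "iNoun of * P1 * [by|through] * P2",
    "iNoun of * P1 * [with|to|on] * P2",
    "iNoun between * P1 * and * P2",
    "complex between * P1 * and * P2",
    "complex of * P1 * and * P2",
    "P1 * form * complex with * iVerb * P2",
    "P1 * P2 * iNoun",
    "P1 depend of P2",
    "between P1 and P2",
)


@dataclass(frozen=True)
class Element:
    kind: str  # literal | P1 | P2 | IVERB | INOUN | ALT | WILDCARD
    stems: tuple[str, ...] = ()  # for literal (one stem) and ALT


@dataclass(frozen=True)
class PatternSpec:
    id: int
    elements: tuple[Element, ...]


def parse_pattern(pattern_id: int, text: str) -> PatternSpec:
    elements: list[Element] = []
    for item in text.split():
        if item == "*":
            elements.append(Element("WILDCARD"))
        elif item in ("P1", "P2"):
            elements.append(Element(item))
        elif item == "iVerb":
            elements.append(Element("IVERB"))
        elif item == "iNoun":
            elements.append(Element("INOUN"))
        elif item.startswith("[") and item.endswith("]"):
            alts = tuple(porter_stem(w) for w in item[1:-1].split("|"))
            elements.append(Element("ALT", alts))
        else:
            elements.append(Element("literal", (porter_stem(item),)))
    if not elements:
        raise ValueError(f"pattern {pattern_id} is empty")
    return PatternSpec(id=pattern_id, elements=tuple(elements))


def compile_patterns(lexicon: KeywordLexicon,
                     strings: Sequence[str] = PATTERN_STRINGS) -> list[PatternSpec]:
    return [parse_pattern(i + 1, s) for i, s in enumerate(strings)]


def load_pattern_file(path) -> tuple[str, ...]:
    """Read an override pattern file: one pattern string per line."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    return tuple(ln for ln in lines if ln and not ln.startswith("#"))


def _element_matches(el: Element, tok: Token, lexicon: KeywordLexicon) -> bool:
    if el.kind == "P1":
        return tok.surface == "PROT1"
    if el.kind == "P2":
        return tok.surface == "PROT2"
    if el.kind == "IVERB":
        return tok.stem in lexicon.iverb
    if el.kind == "INOUN":
        return tok.stem in lexicon.inoun
    return tok.stem in el.stems  # literal / ALT


def _match_from(elements: Sequence[Element], tokens: Sequence[Token], ti: int,
                lexicon: KeywordLexicon, wildcard_limit: int) -> bool:
    if not elements:
        return True
    el = elements[0]
    if el.kind == "WILDCARD":
        for skip in range(0, wildcard_limit + 1):
            if ti + skip > len(tokens):
                break
            if _match_from(elements[1:], tokens, ti + skip,
                           lexicon, wildcard_limit):
                return True
        return False
    if ti >= len(tokens):
        return False
    return (_element_matches(el, tokens[ti], lexicon)
            and _match_from(elements[1:], tokens, ti + 1,
                            lexicon, wildcard_limit))


def match_pattern(spec: PatternSpec, instance: Instance,
                  lexicon: KeywordLexicon,
                  wildcard_limit: int = WILDCARD_LIMIT,
                  blinded: Optional[Sequence[Token]] = None) -> bool:
    if blinded is None:
        blinded = blind_proteins(instance)
    words = [t for t in blinded if t.is_word]
    return any(_match_from(spec.elements, words, start, lexicon, wildcard_limit)
               for start in range(len(words)))


def pattern_vector(instance: Instance, specs: Sequence[PatternSpec],
                   lexicon: KeywordLexicon,
                   wildcard_limit: int = WILDCARD_LIMIT) -> list[bool]:
    blinded = blind_proteins(instance)
    return [match_pattern(s, instance, lexicon, wildcard_limit, blinded=blinded)
            for s in specs]
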