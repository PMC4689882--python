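"""Sentence-level lexical features for a protein-pair instance.

All word distances count word tokens strictly between two anchors; standalone
punctuation tokens never enter distances. The keyword of an instance is the
lexicon word (by Porter stem) minimizing the summed distance to the two
proteins, leftmost on ties. Features that need a keyword fall back to
sentinels (-1 / "none" / False) when no lexicon word occurs.
"""

from __future__ import annotations

from typing import Optional

from .corpus_io import Instance, Token
from .lexicon import KeywordLexicon

DIST_SENTINEL = -1

#: separators that keep two protein names "adjacent" for the parallel feature
_PARALLEL_SEPARATORS = {"—", "-", "--", "/", "and", "or", "("}


def _word_tokens(instance: Instance) -> list[Token]:
    return instance.sentence.word_tokens()


def _protein_indices(instance: Instance) -> set[int]:
    out: set[int] = set()
    for m in instance.sentence.mentions:
        out.update(range(*m.token_span))
    return out


def _anchor_p1(instance: Instance) -> int:
    return instance.p1.token_span[1] - 1  # inner edge: last word of the span


def _anchor_p2(instance: Instance) -> int:
    return instance.p2.token_span[0]  # inner edge: first word of the span


def _between(i: int, j: int) -> range:
    lo, hi = sorted((i, j))
    return range(lo + 1, hi)


def _pair_indices(instance: Instance) -> set[int]:
    return set(range(*instance.p1.token_span)) \
        | set(range(*instance.p2.token_span))


def _words_between(instance: Instance, i: int, j: int) -> int:
    """Word tokens strictly between two positions; the pair's own protein
    tokens do not count as intervening words."""
    skip = _pair_indices(instance)
    return sum(1 for idx in _between(i, j) if idx not in skip)


def _span_gap(instance: Instance, k: int, span: tuple[int, int]) -> int:
    """Distance between index k and the nearest edge of a mention span."""
    if k < span[0]:
        return _words_between(instance, k, span[0])
    if k >= span[1]:
        return _words_between(instance, span[1] - 1, k)
    return 0


def select_keyword(instance: Instance, lexicon: KeywordLexicon) -> Optional[Token]:
    """The lexicon word closest (summed word distance) to the protein pair."""
    prot = _protein_indices(instance)
    best: Optional[Token] = None
    best_cost: Optional[int] = None
    for tok in _word_tokens(instance):
        if tok.index in prot or tok.stem not in lexicon.keywords:
            continue
        cost = (_span_gap(instance, tok.index, instance.p1.token_span)
                + _span_gap(instance, tok.index, instance.p2.token_span))
        if best_cost is None or cost < best_cost:
            best, best_cost = tok, cost
    return best


def distance_features(instance: Instance,
                      keyword: Optional[Token]) -> tuple[int, int, int]:
    """(type1, type2, type3): words between (P1,K), (P2,K), (P1,P2)."""
    type3 = _words_between(instance, _anchor_p1(instance), _anchor_p2(instance))
    if keyword is None:
        return (DIST_SENTINEL, DIST_SENTINEL, type3)
    k = keyword.index
    return (_span_gap(instance, k, instance.p1.token_span),
            _span_gap(instance, k, instance.p2.token_span), type3)


def keyword_position(instance: Instance, keyword: Optional[Token]) -> str:
    """infix ([P1-K-P2]), prefix ([K-P1-P2]) or postfix ([P1-P2-K])."""
    if keyword is None:
        return "none"
    k = keyword.index
    if k < instance.p1.token_span[0]:
        return "prefix"
    if k >= instance.p2.token_span[1]:
        return "postfix"
    return "infix"


def protein_positions(instance: Instance) -> tuple[int, int]:
    """1-based word positions of P1 and P2 in the sentence."""
    return (instance.p1.token_span[0] + 1, instance.p2.token_span[0] + 1)


def _comma_between(instance: Instance, i: int, j: int) -> bool:
    words = _word_tokens(instance)
    lo_tok, hi_tok = words[min(i, j)], words[max(i, j)]
    return any(t.surface == "," and not t.is_word
               and lo_tok.char_end <= t.char_start < hi_tok.char_start
               for t in instance.sentence.tokens)


def comma_feature(instance: Instance, keyword: Optional[Token]) -> str:
    """Comma presence in the two gaps of the position-ordered anchors."""
    if keyword is None:
        return "none"
    anchors = sorted([_anchor_p1(instance), _anchor_p2(instance), keyword.index])
    first = _comma_between(instance, anchors[0], anchors[1])
    second = _comma_between(instance, anchors[1], anchors[2])
    return ("y" if first else "n") + ("y" if second else "n")


def _stem_between_anchors(instance: Instance, keyword: Optional[Token],
                          stems: frozenset[str]) -> bool:
    """Does any of `stems` occur between the proteins, or between the keyword
    and either protein?"""
    p1, p2 = _anchor_p1(instance), _anchor_p2(instance)
    gaps = [(p1, p2)]
    if keyword is not None:
        gaps += [(keyword.index, p1), (keyword.index, p2)]
    words = _word_tokens(instance)
    for a, b in gaps:
        for i in _between(a, b):
            if words[i].stem in stems:
                return True
    return False


def boolean_flags(instance: Instance, keyword: Optional[Token],
                  lexicon: KeywordLexicon) -> tuple[bool, bool, bool, bool, bool]:
    """(negative, conjunctive, which, but, condition).

    Negation and condition words must occur between the anchors; conjunctive
    words, "which" and "but" count anywhere in the sentence.
    """
    surfaces = {t.surface.lower() for t in _word_tokens(instance)}
    negative = _stem_between_anchors(instance, keyword, lexicon.negatives)
    condition = _stem_between_anchors(
        instance, keyword, frozenset(lexicon.condition_words))
    conjunctive = bool(surfaces & lexicon.conjunctives)
    return (negative, conjunctive, "which" in surfaces, "but" in surfaces,
            condition)


def preposition_of_keyword(instance: Instance, keyword: Optional[Token],
                           lexicon: KeywordLexicon) -> str:
    """Nearest preposition following the keyword within word distance 3."""
    if keyword is None:
        return "none"
    words = _word_tokens(instance)
    for i in range(keyword.index + 1, min(keyword.index + 5, len(words))):
        if words[i].surface.lower() in lexicon.prepositions:
            return words[i].surface.lower()
    return "none"


def multiple_and_second_keywords(
        instance: Instance, keyword: Optional[Token],
        lexicon: KeywordLexicon) -> tuple[bool, dict[str, bool]]:
    """(multiple-keyword flag, per-second-keyword flags).

    A second keyword fires when it occurs strictly between the proteins and is
    not the stem selected as the instance's keyword.
    """
    prot = _protein_indices(instance)
    words = _word_tokens(instance)
    n_kw = sum(1 for t in words
               if t.index not in prot and t.stem in lexicon.keywords)
    multiple = n_kw >= 2
    kstem = keyword.stem if keyword is not None else None
    between = {words[i].stem
               for i in _between(_anchor_p1(instance), _anchor_p2(instance))}
    second = {w: (w != kstem and w in between) for w in lexicon.second_keywords}
    return multiple, second


def parallel_expression(instance: Instance) -> bool:
    """True when P1 and P2 are adjacent or separated only by parallel-
    expression separators (dash, slash, and, or, open parenthesis)."""
    lo = _anchor_p1(instance)
    hi = instance.p2.token_span[0]
    if hi <= lo:
        return True
    words = _word_tokens(instance)
    lo_tok, hi_tok = words[lo], words[hi]
    for t in instance.sentence.tokens:
        if t.char_start < lo_tok.char_end or t.char_start >= hi_tok.char_start:
            continue
        if t.surface.lower() not in _PARALLEL_SEPARATORS:
            return False
    return True
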