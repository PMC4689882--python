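"""Corpus reading, tokenization and instance enumeration.

Reads the unified XML interchange format shared by the public PPI benchmark
corpora (corpus > document > sentence > entity / pair), turns each sentence
into word tokens whose indices back the word-distance features, and expands
every sentence into one instance per unordered protein-mention pair.

Conventions: character offsets are 0-based half-open internally (the XML
``charOffset`` attribute uses the corpora's inclusive ``start-end`` form and
is converted on read/write); token indices are 0-based and count word tokens
only — standalone punctuation (commas, semicolons, parentheses) is kept as
non-word tokens that never enter distance computations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from lxml import etree

from .stem import porter_stem

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

#: chunks that become standalone non-word tokens
_PUNCT_TOKENS = {",", ";", "(", ")", "/", "-", "--", "—"}
#: characters peeled off word edges into non-word tokens
_SPLIT_PUNCT = ",;()"
#: characters silently stripped from word edges
_STRIP_PUNCT = '.!?:"“”‘’\''


@dataclass
class Token:
    surface: str
    stem: str
    index: Optional[int]  # 0-based among word tokens; None for punctuation
    is_word: bool
    char_start: int
    char_end: int


@dataclass
class ProteinMention:
    id: str
    char_start: int
    char_end: int
    token_span: tuple[int, int] = (0, 0)  # half-open word-token index range

    @property
    def token_start(self) -> int:
        return self.token_span[0]


@dataclass
class Sentence:
    id: str
    text: str
    tokens: list[Token] = field(default_factory=list)
    mentions: list[ProteinMention] = field(default_factory=list)
    pairs: list[tuple[str, str, bool]] = field(default_factory=list)
    tree: Optional[object] = None  # ParseTree, attached separately

    def word_tokens(self) -> list[Token]:
        return [t for t in self.tokens if t.is_word]


@dataclass
class Instance:
    id: str
    sentence: Sentence
    p1: ProteinMention
    p2: ProteinMention
    label: str = UNKNOWN
    keyword: Optional[Token] = None
    dk: Optional[int] = None
    features: dict = field(default_factory=dict)


def _merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def tokenize(text: str, mention_spans: Iterable[tuple[int, int]] = ()) -> list[Token]:
    """Tokenize a sentence, collapsing each protein mention to one token.

    Mention character spans are atomic: a multi-word protein name becomes a
    single word token, so word distances involving proteins count the name as
    one word.
    """
    for s, e in mention_spans:
        if not (0 <= s < e <= len(text)):
            raise ValueError(f"mention offsets ({s},{e}) outside sentence")
    atomic = _merge_spans(mention_spans)
    tokens: list[Token] = []

    def emit(chunk: str, start: int, is_atomic: bool) -> None:
        if is_atomic:
            tokens.append(Token(chunk, porter_stem(chunk.lower()), None, True,
                                start, start + len(chunk)))
            return
        # peel leading split-punctuation
        while chunk and chunk[0] in _SPLIT_PUNCT:
            tokens.append(Token(chunk[0], chunk[0], None, False, start, start + 1))
            chunk, start = chunk[1:], start + 1
        chunk = chunk.lstrip(_STRIP_PUNCT)
        # peel trailing punctuation (emitted after the word)
        trail: list[Token] = []
        end = start + len(chunk)
        while chunk:
            if chunk[-1] in _SPLIT_PUNCT:
                trail.append(Token(chunk[-1], chunk[-1], None, False, end - 1, end))
                chunk, end = chunk[:-1], end - 1
            elif chunk[-1] in _STRIP_PUNCT:
                chunk, end = chunk[:-1], end - 1
            else:
                break
        if chunk:
            if chunk in _PUNCT_TOKENS:
                tokens.append(Token(chunk, chunk, None, False, start, end))
            else:
                tokens.append(Token(chunk, porter_stem(chunk.lower()), None,
                                    True, start, end))
        tokens.extend(reversed(trail))

    pos = 0
    bounds = iter(atomic)
    nxt = next(bounds, None)
    while pos < len(text):
        if nxt and pos == nxt[0]:
            emit(text[nxt[0]:nxt[1]], nxt[0], True)
            pos = nxt[1]
            nxt = next(bounds, None)
            continue
        stop = nxt[0] if nxt else len(text)
        if text[pos].isspace():
            pos += 1
            continue
        end = pos
        while end < stop and not text[end].isspace():
            end += 1
        emit(text[pos:end], pos, False)
        pos = end

    idx = 0
    for t in tokens:
        if t.is_word:
            t.index = idx
            idx += 1
    return tokens


def _align_mention(sentence: Sentence, mention: ProteinMention) -> None:
    idxs = [t.index for t in sentence.tokens
            if t.is_word and t.char_start < mention.char_end
            and t.char_end > mention.char_start]
    if not idxs:
        raise ValueError(
            f"mention {mention.id} does not align with any word token")
    mention.token_span = (min(idxs), max(idxs) + 1)


def build_sentence(sid: str, text: str,
                   mentions: list[ProteinMention],
                   pairs: list[tuple[str, str, bool]] | None = None) -> Sentence:
    sent = Sentence(id=sid, text=text, mentions=mentions, pairs=pairs or [])
    sent.tokens = tokenize(text, [(m.char_start, m.char_end) for m in mentions])
    for m in mentions:
        _align_mention(sent, m)
    return sent


def read_unified_xml(path) -> list[Sentence]:
    """Read a unified-format PPI corpus file.

    Every annotated pair with ``interaction="True"`` marks a positive gold
    pair; all other mention pairs are negative.
    """
    tree = etree.parse(str(path))
    sentences: list[Sentence] = []
    for sel in tree.iter("sentence"):
        sid = sel.get("id")
        text = sel.get("text", "")
        mentions = []
        ids = set()
        for eel in sel.iter("entity"):
            off = eel.get("charOffset", "")
            first = off.split(",")[0]
            try:
                a, b = first.split("-")
                start, end = int(a), int(b) + 1
            except ValueError as exc:
                raise ValueError(
                    f"entity {eel.get('id')}: bad charOffset {off!r}") from exc
            mentions.append(ProteinMention(eel.get("id"), start, end))
            ids.add(eel.get("id"))
        pairs = []
        for pel in sel.iter("pair"):
            e1, e2 = pel.get("e1"), pel.get("e2")
            if e1 not in ids or e2 not in ids:
                raise ValueError(
                    f"pair {pel.get('id')} in sentence {sid} references "
                    f"unknown entity ({e1}, {e2})")
            pairs.append((e1, e2, pel.get("interaction", "").lower() == "true"))
        sentences.append(build_sentence(sid, text, mentions, pairs))
    return sentences


def enumerate_instances(sentence: Sentence, labeled: bool = True) -> list[Instance]:
    """One instance per unordered mention pair, P1 first in token order.

    Each occurrence of the same protein pair counts as a separate instance.
    """
    positive = {frozenset((e1, e2)) for e1, e2, inter in sentence.pairs if inter}
    out = []
    ordered = sorted(sentence.mentions,
                     key=lambda m: (m.token_start, m.char_start, m.id))
    for a, b in itertools.combinations(ordered, 2):
        if labeled:
            label = POSITIVE if frozenset((a.id, b.id)) in positive else NEGATIVE
        else:
            label = UNKNOWN
        out.append(Instance(id=f"{sentence.id}|{a.id}|{b.id}",
                            sentence=sentence, p1=a, p2=b, label=label))
    return out


def blind_proteins(instance: Instance) -> list[Token]:
    """Blinded copy of the sentence tokens: P1 -> PROT1, P2 -> PROT2,
    any other protein mention -> PROT."""
    sent = instance.sentence
    span_sub: dict[int, str] = {}
    for m in sent.mentions:
        for i in range(*m.token_span):
            span_sub.setdefault(i, "PROT")
    for i in range(*instance.p1.token_span):
        span_sub[i] = "PROT1"
    for i in range(*instance.p2.token_span):
        span_sub[i] = "PROT2"
    out = []
    for t in sent.tokens:
        if t.is_word and t.index in span_sub:
            name = span_sub[t.index]
            out.append(replace(t, surface=name, stem=name.lower()))
        else:
            out.append(replace(t))
    return out


def read_parse_trees(path) -> dict:
    """Read ``sentence-id<TAB>bracketed-tree`` lines into a dict of ParseTree."""
    from .parse_features import parse_bracketed

    trees = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                sid, bracketed = line.split("\t", 1)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected id<TAB>tree") from exc
            try:
                trees[sid] = parse_bracketed(bracketed)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return trees


def attach_trees(sentences: Iterable[Sentence], trees: dict) -> None:
    for s in sentences:
        s.tree = trees.get(s.id)


def write_feature_matrix(instances: Iterable[Instance], path) -> None:
    import pandas as pd

    from .features import FEATURE_NAMES

    rows = []
    for inst in instances:
        row = {"instance_id": inst.id, "label": inst.label,
               "dk": -1 if inst.dk is None else inst.dk}
        for name in FEATURE_NAMES:
            row[name] = inst.features[name]
        rows.append(row)
    pd.DataFrame(rows, columns=["instance_id", "label", "dk"] + list(FEATURE_NAMES)
                 ).to_csv(path, index=False)


def read_feature_matrix(path):
    """Read a feature-matrix CSV back into (instance_id, label, dk, features) rows."""
    import pandas as pd

    from .features import FEATURE_KINDS, FEATURE_NAMES

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        feats = {}
        for name in FEATURE_NAMES:
            kind = FEATURE_KINDS[name]
            raw = r[name]
            if kind == "int":
                feats[name] = int(raw)
            elif kind == "bool":
                feats[name] = raw == "True"
            else:
                feats[name] = raw
        dk = int(r["dk"])
        out.append((r["instance_id"], r["label"], None if dk < 0 else dk, feats))
    return out
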