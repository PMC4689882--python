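"""Synthetic PPI corpus generator with planted dominant-keyword ground truth.

Each generated sentence contains two blinded-able protein mentions, one
interaction keyword drawn either as the *designated dominant keyword* or as a
distractor, and a hand-written template (with a fixed bracketed parse tree)
from one of the three keyword-position families (S-V-O for infix, phrase
expressions for prefix, parallel/inverted expressions for postfix).

Generative rule per pair:

* dominant keyword present  -> planted_dk = 1; label positive with
  probability ``dominance`` (the keyword drives the label);
* distractor keyword        -> planted_dk = 0; label ~ Bernoulli(positive_rate),
  independent of the keyword. The label is then surfaced through non-keyword
  cues: negative labels preferentially use negation-cue templates ("does not
  ...", "but not ...") with probability ``signal_fidelity``. This mirrors the
  modelling premise that instances without a dominant keyword are classifiable
  from features other than the keyword.

With dominance = 1.0 the unbalance degree of the dominant keyword is exactly
1, so the planted flags are the ground truth that DK refinement should
recover.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from . import parse_features
from .corpus_io import (
    Instance,
    NEGATIVE,
    POSITIVE,
    ProteinMention,
    Sentence,
    build_sentence,
    enumerate_instances,
    read_parse_trees,
    read_unified_xml,
)
from .lexicon import KeywordLexicon, default_lexicon
from .stem import porter_stem

#: (base, 3sg verb, plural verb, noun) surface forms; the first entry is the
#: designated dominant keyword, the rest serve as distractors.
KEYWORD_FORMS: tuple[tuple[str, str, str, str], ...] = (
    ("interact", "interacts", "interact", "interaction"),
    ("bind", "binds", "bind", "binding"),
    ("regulate", "regulates", "regulate", "regulation"),
    ("activate", "activates", "activate", "activation"),
    ("stimulate", "stimulates", "stimulate", "stimulation"),
    ("inhibit", "inhibits", "inhibit", "inhibition"),
    ("associate", "associates", "associate", "association"),
    ("mediate", "mediates", "mediate", "mediation"),
)

NOISE_WORDS: tuple[str, ...] = (
    "kinase", "receptor", "enzyme", "domain", "subunit", "residue",
    "mutant", "homolog", "plasmid", "vector", "strain", "tissue",
    "membrane", "sample", "fragment", "cluster",
)

_PROTEIN_ALPHABET = "ABCDEFGHJKLMNQRSTUVWXYZ"


@dataclass
class SyntheticConfig:
    n_sentences: int = 500
    positive_rate: float = 0.3
    #: P(label = positive | dominant keyword present)
    dominance: float = 1.0
    #: share of sentences whose keyword slot takes the dominant keyword
    dominant_share: float = 0.4
    #: how reliably non-keyword cues surface the label of planted_dk=0 pairs
    signal_fidelity: float = 0.85
    position_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    n_distractor_keywords: int = 4
    noise_word_pool: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.positive_rate, self.dominance, self.dominant_share,
                  self.signal_fidelity, *self.position_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.position_mix) - 1.0) > 1e-9:
            raise ValueError("position_mix must sum to 1")
        if not 1 <= self.n_distractor_keywords < len(KEYWORD_FORMS):
            raise ValueError("n_distractor_keywords out of range")
        if not 1 <= self.noise_word_pool <= len(NOISE_WORDS):
            raise ValueError("noise_word_pool out of range")


@dataclass
class SyntheticCorpus:
    sentences: list[Sentence]
    instances: list[Instance]
    planted_dk: dict[str, int]
    config: SyntheticConfig = field(default_factory=SyntheticConfig)

    @property
    def dominant_stem(self) -> str:
        return porter_stem(KEYWORD_FORMS[0][0])


def load_templates() -> list[dict]:
    ref = importlib.resources.files("dkppi.data") / "synthetic_templates.json"
    return json.loads(ref.read_text(encoding="utf-8"))["templates"]


def _protein_names(rng: np.random.Generator, n: int = 2) -> list[str]:
    names = set()
    while len(names) < n:
        letters = rng.choice(list(_PROTEIN_ALPHABET), size=3)
        names.add("P" + "".join(letters))
    return sorted(names)


def _fill(s: str, slots: dict[str, str]) -> str:
    for key, value in slots.items():
        s = s.replace("{" + key + "}", value)
    return s


def generate(config: SyntheticConfig,
             lexicon: KeywordLexicon | None = None) -> SyntheticCorpus:
    """Generate a corpus; deterministic for a fixed config (incl. seed)."""
    lexicon = lexicon or default_lexicon()
    templates = load_templates()
    by_family: dict[tuple[str, bool], list[dict]] = {}
    for t in templates:
        by_family.setdefault((t["position"], t["cue"]), []).append(t)

    noise = NOISE_WORDS[: config.noise_word_pool]
    for w in noise:
        assert porter_stem(w) not in lexicon.keywords, \
            f"noise word {w!r} collides with the keyword lexicon"
    keywords = KEYWORD_FORMS[: 1 + config.n_distractor_keywords]

    rng = np.random.default_rng(config.seed)
    positions = ("infix", "prefix", "postfix")
    sentences: list[Sentence] = []
    instances: list[Instance] = []
    planted: dict[str, int] = {}

    for i in range(config.n_sentences):
        sid = f"synth.d0.s{i}"
        position = positions[rng.choice(3, p=list(config.position_mix))]
        is_dominant = bool(rng.random() < config.dominant_share)
        if is_dominant:
            kw = keywords[0]
            dk = 1
            label = POSITIVE if rng.random() < config.dominance else NEGATIVE
            cue = False
        else:
            kw = keywords[1 + int(rng.integers(len(keywords) - 1))]
            dk = 0
            label = POSITIVE if rng.random() < config.positive_rate else NEGATIVE
            faithful = bool(rng.random() < config.signal_fidelity)
            cue = (label == NEGATIVE) == faithful

        family = by_family[(position, cue)]
        template = family[int(rng.integers(len(family)))]
        p1_name, p2_name = _protein_names(rng)
        slots = {
            "P1": p1_name, "P2": p2_name,
            "KV0": kw[0], "KV": kw[1], "KVP": kw[2], "KN": kw[3],
            "N1": noise[int(rng.integers(len(noise)))],
        }
        words = [_fill(tok, slots) for tok in template["tokens"]]

        text = ""
        offsets: dict[str, tuple[int, int]] = {}
        for raw, filled in zip(template["tokens"], words):
            if text:
                text += " "
            start = len(text)
            text += filled
            if raw in ("{P1}", "{P2}"):
                offsets[raw] = (start, len(text))

        mentions = [
            ProteinMention(f"{sid}.e0", *offsets["{P1}"]),
            ProteinMention(f"{sid}.e1", *offsets["{P2}"]),
        ]
        pairs = [(f"{sid}.e0", f"{sid}.e1", label == POSITIVE)]
        sentence = build_sentence(sid, text, mentions, pairs)
        sentence.tree = parse_features.parse_bracketed(
            _fill(template["tree"], slots))
        n_leaves = len(sentence.tree.leaves())
        n_words = len(sentence.word_tokens())
        assert n_leaves == n_words, \
            f"template tree/token mismatch ({n_leaves} != {n_words})"
        sentences.append(sentence)
        for inst in enumerate_instances(sentence):
            instances.append(inst)
            planted[inst.id] = dk

    return SyntheticCorpus(sentences=sentences, instances=instances,
                           planted_dk=planted, config=config)


def export(corpus: SyntheticCorpus, directory) -> tuple[Path, Path]:
    """Write the corpus as unified XML plus a bracketed-tree file."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    root = etree.Element("corpus", source="dkppi-synthetic")
    doc = etree.SubElement(root, "document", id="synth.d0")
    for sent in corpus.sentences:
        sel = etree.SubElement(doc, "sentence", id=sent.id, text=sent.text)
        for m in sent.mentions:
            etree.SubElement(
                sel, "entity", id=m.id, type="protein",
                charOffset=f"{m.char_start}-{m.char_end - 1}",
                text=sent.text[m.char_start:m.char_end])
        for j, (e1, e2, inter) in enumerate(sent.pairs):
            etree.SubElement(sel, "pair", id=f"{sent.id}.p{j}", e1=e1, e2=e2,
                             interaction=str(inter))
    xml_path = d / "corpus.xml"
    etree.ElementTree(root).write(str(xml_path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")
    tree_path = d / "trees.ptb"
    with open(tree_path, "w", encoding="utf-8") as fh:
        for sent in corpus.sentences:
            fh.write(f"{sent.id}\t{parse_features.to_bracketed(sent.tree)}\n")
    return xml_path, tree_path


def load_exported(xml_path, tree_path) -> tuple[list[Sentence], list[Instance]]:
    """Round-trip helper: read back an exported corpus."""
    sentences = read_unified_xml(xml_path)
    trees = read_parse_trees(tree_path)
    for s in sentences:
        s.tree = trees.get(s.id)
    all_instances = [i for s in sentences for i in enumerate_instances(s)]
    return sentences, all_instances
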