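import numpy as np
import pytest

from dkppi.corpus_io import ProteinMention, build_sentence, enumerate_instances
from dkppi.lexicon import default_lexicon
from dkppi.parse_features import parse_bracketed


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_instance(text, p1, p2, extra_mentions=(), tree=None, label_positive=True,
                  pair=None):
    """Build a one-sentence instance from a raw sentence string.

    p1/p2/extra_mentions are surface substrings located by first occurrence
    (searching left to right, so repeated names can be addressed in order).
    """
    mentions = []
    cursor = {}
    names = [p1, p2, *extra_mentions]
    for i, name in enumerate(names):
        start = text.index(name, cursor.get(name, 0))
        cursor[name] = start + len(name)
        mentions.append(ProteinMention(f"e{i}", start, start + len(name)))
    pairs = [("e0", "e1", label_positive)]
    sent = build_sentence("s0", text, mentions, pairs)
    if tree is not None:
        sent.tree = parse_bracketed(tree)
    instances = enumerate_instances(sent)
    for inst in instances:
        if {inst.p1.id, inst.p2.id} == {"e0", "e1"}:
            return inst
    raise AssertionError("pair instance not found")


DRIVEN_TREE = ("(S (NP (NN P1)) (VP (VBZ is) (VP (VBN driven) "
               "(PP (IN by) (NP (NN P2))))))")


@pytest.fixture
def driven_instance():
    """The worked example 'P1 is driven by P2' with its parse tree."""
    return make_instance("P1 is driven by P2", "P1", "P2", tree=DRIVEN_TREE)


class OracleLearner:
    """Label-memorizing classifier keyed on the encoded feature row.

    Consistent only when the feature row determines the label, which holds
    for synthetic corpora generated with signal_fidelity=1 and dominance=1.
    """

    def __init__(self, table, majority):
        self.table = table
        self.majority = majority

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.table.get(tuple(row), self.majority)
                         for row in np.asarray(X)])


def oracle_factory(instances, encoder):
    from dkppi.corpus_io import POSITIVE

    X = encoder.transform([i.features for i in instances])
    y = [1 if i.label == POSITIVE else 0 for i in instances]
    table = {}
    for row, lab in zip(X, y):
        key = tuple(row)
        assert table.get(key, lab) == lab, "oracle requires consistent labels"
        table[key] = lab
    majority = int(round(np.mean(y)))
    return lambda: OracleLearner(table, majority)
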