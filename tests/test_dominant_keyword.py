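"""Unbalance degree, the three update cases, and refinement behaviour."""

import numpy as np
import pytest

from dkppi.corpus_io import NEGATIVE, POSITIVE
from dkppi.dominant_keyword import (
    DKConfig,
    DKState,
    MajorityClassifier,
    default_learner,
    initial_dk,
    predict_dk,
    refine_dk,
    train_c0_c1,
    train_dk_classifier,
    unbalance_degree,
    update_dk_fold,
    read_dk_state,
    write_dk_state,
)
from dkppi.features import FeatureEncoder, extract_all
from dkppi.synthetic_data import SyntheticConfig, generate

from conftest import make_instance, oracle_factory


def keyword_instances(lexicon, spec):
    """Instances sharing keyword surfaces per (text_keyword, positive) spec."""
    out = []
    for i, (kw_word, positive) in enumerate(spec):
        inst = make_instance(f"P1 {kw_word} P2", "P1", "P2",
                             label_positive=positive)
        inst.id = f"i{i}"
        out.append(inst)
    extract_all(out, lexicon)
    return out


class TestUnbalanceDegree:
    def test_direct_ratio(self, lexicon):
        insts = keyword_instances(lexicon, [("binds", True)] * 3
                                  + [("binds", False)])
        assert unbalance_degree("bind", insts) == pytest.approx(0.75)

    def test_completely_unbalanced(self, lexicon):
        pos = keyword_instances(lexicon, [("binds", True)] * 4)
        neg = keyword_instances(lexicon, [("binds", False)] * 4)
        assert unbalance_degree("bind", pos) == 1.0
        assert unbalance_degree("bind", neg) == 0.0

    def test_completely_balanced(self, lexicon):
        insts = keyword_instances(lexicon, [("binds", True), ("binds", True),
                                            ("binds", False), ("binds", False)])
        assert unbalance_degree("bind", insts) == 0.5

    def test_unknown_keyword_errors(self, lexicon):
        insts = keyword_instances(lexicon, [("binds", True)])
        with pytest.raises(ValueError):
            unbalance_degree("interact", insts)


class TestInitialDK:
    def test_high_unbalance_marks_dk1(self, lexicon):
        # U(bind) = 0.9 -> 1-U = 0.1 < 0.15 -> DK=1
        insts = keyword_instances(lexicon, [("binds", True)] * 9
                                  + [("binds", False)])
        state = initial_dk(insts, DKConfig(threshold_T=0.15))
        assert all(state.dk[i.id] == 1 for i in insts)

    def test_balanced_keyword_stays_dk0(self, lexicon):
        insts = keyword_instances(lexicon, [("binds", True), ("binds", False)])
        state = initial_dk(insts, DKConfig(threshold_T=0.15))
        assert all(state.dk[i.id] == 0 for i in insts)

    def test_threshold_is_strict(self, lexicon):
        # U = 0.85 -> min(U, 1-U) = 0.15, not < 0.15 -> DK=0
        spec = [("binds", True)] * 17 + [("binds", False)] * 3
        state = initial_dk(keyword_instances(lexicon, spec),
                           DKConfig(threshold_T=0.15))
        assert set(state.dk.values()) == {0}

    def test_keywordless_instance_is_dk0(self, lexicon):
        inst = make_instance("P1 near P2", "P1", "P2")
        inst.id = "i0"
        extract_all([inst], lexicon)
        state = initial_dk([inst], DKConfig())
        assert state.dk["i0"] == 0


class _FixedClassifier:
    """Predicts a fixed label for every instance."""

    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


def _fold_setup(lexicon, labels):
    insts = keyword_instances(
        lexicon, [("binds", lab == POSITIVE) for lab in labels])
    encoder = FeatureEncoder().fit([i.features for i in insts])
    state = DKState(dk={i.id: 0 for i in insts})
    return insts, encoder, state


class TestUpdateCases:
    def test_case1_follows_correct_classifier(self, lexicon):
        insts, encoder, state = _fold_setup(lexicon, [POSITIVE])
        rng = np.random.default_rng(0)
        # C0 wrong (predicts 0), C1 right (predicts 1) -> dk := 1
        update_dk_fold(insts, _FixedClassifier(0), _FixedClassifier(1),
                       state, DKConfig(), rng, encoder)
        assert state.dk["i0"] == 1
        # now C0 right, C1 wrong -> dk := 0 despite current value
        update_dk_fold(insts, _FixedClassifier(1), _FixedClassifier(0),
                       state, DKConfig(), rng, encoder)
        assert state.dk["i0"] == 0

    def test_case2_never_touches_positives(self, lexicon):
        insts, encoder, state = _fold_setup(lexicon, [POSITIVE])
        rng = np.random.default_rng(0)
        update_dk_fold(insts, _FixedClassifier(1), _FixedClassifier(1),
                       state, DKConfig(mutation_alpha=1.0), rng, encoder)
        assert state.dk["i0"] == 0 and not state.removed

    def test_case2_mutates_true_negatives_at_alpha(self, lexicon):
        insts, encoder, state = _fold_setup(lexicon, [NEGATIVE] * 50)
        rng = np.random.default_rng(0)
        stats = update_dk_fold(insts, _FixedClassifier(0), _FixedClassifier(0),
                               state, DKConfig(mutation_alpha=1.0), rng, encoder)
        assert stats["mutations"] == 50
        assert all(v == 1 for v in state.dk.values())

    def test_case3_removes_only_gold_negatives(self, lexicon):
        insts, encoder, state = _fold_setup(lexicon, [NEGATIVE, POSITIVE])
        rng = np.random.default_rng(0)
        # both classifiers wrong for both instances
        preds = {insts[0].id: 1, insts[1].id: 0}

        class Wrong:
            def predict(self_inner, X):
                return np.array([preds[i.id] for i in insts])

        update_dk_fold(insts, Wrong(), Wrong(), state, DKConfig(), rng, encoder)
        assert state.removed == {insts[0].id}
        assert insts[1].id in state.dk


class TestTrainC0C1:
    def test_two_fitted_classifiers(self, lexicon):
        insts = keyword_instances(
            lexicon, [("binds", True), ("binds", False),
                      ("activates", True), ("activates", False)])
        encoder = FeatureEncoder().fit([i.features for i in insts])
        state = DKState(dk={"i0": 1, "i1": 1, "i2": 0, "i3": 0})
        c0, c1 = train_c0_c1(insts, state, default_learner(0, 10), encoder)
        X = encoder.transform([i.features for i in insts])
        assert len(c0.predict(X)) == 4 and len(c1.predict(X)) == 4

    def test_empty_side_degrades_to_majority(self, lexicon):
        insts = keyword_instances(lexicon, [("binds", True), ("binds", True),
                                            ("binds", False)])
        encoder = FeatureEncoder().fit([i.features for i in insts])
        state = DKState(dk={i.id: 0 for i in insts})
        _, c1 = train_c0_c1(insts, state, default_learner(0, 10), encoder)
        assert isinstance(c1, MajorityClassifier)
        assert c1.label == 1  # majority of the whole fold


class TestRefinement:
    def test_m0_returns_initial_assignment(self, lexicon):
        corpus = generate(SyntheticConfig(n_sentences=60, seed=5))
        extract_all(corpus.instances, lexicon)
        cfg0 = DKConfig(iterations_m=0, rng_seed=5)
        state = refine_dk(corpus.instances, cfg0, default_learner(5, 10))
        assert state.dk == initial_dk(corpus.instances, cfg0).dk
        assert not state.removed

    def test_oracle_learner_alpha0_is_fixed_point(self, lexicon):
        corpus = generate(SyntheticConfig(
            n_sentences=80, dominance=1.0, signal_fidelity=1.0, seed=6))
        extract_all(corpus.instances, lexicon)
        encoder = FeatureEncoder().fit([i.features for i in corpus.instances])
        learner = oracle_factory(corpus.instances, encoder)
        cfg = DKConfig(mutation_alpha=0.0, iterations_m=3, rng_seed=6)
        state = refine_dk(corpus.instances, cfg, learner, encoder)
        assert state.dk == initial_dk(corpus.instances, cfg).dk
        assert not state.removed
        assert all(h == {"case1": 0, "mutations": 0, "removed": 0}
                   for h in state.history)

    def test_alpha0_refinement_is_deterministic(self, lexicon):
        corpus = generate(SyntheticConfig(n_sentences=60, seed=7))
        extract_all(corpus.instances, lexicon)
        cfg = DKConfig(mutation_alpha=0.0, iterations_m=2, rng_seed=7)
        s1 = refine_dk(corpus.instances, cfg, default_learner(7, 20))
        s2 = refine_dk(corpus.instances, cfg, default_learner(7, 20))
        assert s1.dk == s2.dk and s1.removed == s2.removed

    def test_only_gold_negatives_removed(self, lexicon):
        corpus = generate(SyntheticConfig(n_sentences=120, seed=8))
        extract_all(corpus.instances, lexicon)
        state = refine_dk(corpus.instances, DKConfig(rng_seed=8),
                          default_learner(8, 20))
        labels = {i.id: i.label for i in corpus.instances}
        assert all(labels[iid] == NEGATIVE for iid in state.removed)
        survivors = state.survivors(corpus.instances)
        assert set(state.dk) == {i.id for i in survivors}
        assert set(state.dk.values()) <= {0, 1}


class TestDKClassifier:
    def test_constant_when_single_class(self, lexicon):
        insts = keyword_instances(lexicon, [("binds", True), ("binds", False)])
        encoder = FeatureEncoder().fit([i.features for i in insts])
        state = DKState(dk={i.id: 0 for i in insts})
        model = train_dk_classifier(insts, state, default_learner(0, 10),
                                    encoder)
        assert predict_dk(model, insts) == [0, 0]

    def test_heldout_dk_prediction_accuracy(self, lexicon):
        train = generate(SyntheticConfig(n_sentences=500, dominance=1.0, seed=2))
        test = generate(SyntheticConfig(n_sentences=200, dominance=1.0, seed=102))
        extract_all(train.instances, lexicon)
        extract_all(test.instances, lexicon)
        cfg = DKConfig(rng_seed=2)
        encoder = FeatureEncoder().fit([i.features for i in train.instances])
        state = refine_dk(train.instances, cfg, default_learner(2), encoder)
        model = train_dk_classifier(train.instances, state,
                                    default_learner(2), encoder)
        pred = predict_dk(model, test.instances)
        truth = [test.planted_dk[i.id] for i in test.instances]
        acc = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc >= 0.85


class TestSerialization:
    def test_round_trip(self, tmp_path):
        state = DKState(dk={"a": 1, "b": 0}, removed={"c"})
        path = tmp_path / "dk.csv"
        write_dk_state(state, path)
        back = read_dk_state(path)
        assert back.dk == state.dk and back.removed == state.removed
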