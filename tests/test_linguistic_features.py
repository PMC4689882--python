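"""Worked-example and derived checks for the sentence-level features."""

import pytest

from dkppi import linguistic_features as lf
from dkppi.features import FEATURE_NAMES, extract_features

from conftest import make_instance


class TestKeywordSelection:
    def test_single_lexicon_hit(self, lexicon, driven_instance):
        kw = lf.select_keyword(driven_instance, lexicon)
        assert kw is not None and kw.surface == "driven"

    def test_no_lexicon_hit(self, lexicon):
        inst = make_instance("P1 near P2", "P1", "P2")
        assert lf.select_keyword(inst, lexicon) is None

    def test_nearest_candidate_wins(self, lexicon):
        # "binds": 0 words to P1, 3 to P2 (sum 3); "interacts": 2 and 1 (sum 3)
        # -> tie, leftmost ("binds") wins
        inst = make_instance("P1 binds and interacts with P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert kw.surface == "binds"

    def test_sum_distance_decides(self, lexicon):
        # "binds" sum = 0+3 = 3; "activates" sum = 1+0 = 1 -> activates wins
        inst = make_instance("binds P1 which activates P2", "P1", "P2")
        assert lf.select_keyword(inst, lexicon).surface == "activates"


class TestDistances:
    def test_worked_example(self, lexicon, driven_instance):
        kw = lf.select_keyword(driven_instance, lexicon)
        assert lf.distance_features(driven_instance, kw) == (1, 1, 3)

    def test_adjacency(self, lexicon):
        inst = make_instance("P1 binds P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.distance_features(inst, kw) == (0, 0, 1)

    def test_prefix_keyword_distances(self, lexicon):
        inst = make_instance("binds P1 to P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert kw.surface == "binds"
        assert lf.distance_features(inst, kw) == (0, 1, 1)

    def test_no_keyword_sentinels(self, lexicon):
        inst = make_instance("P1 near the P2", "P1", "P2")
        assert lf.distance_features(inst, None) == (-1, -1, 2)


class TestPositionsAndComma:
    @pytest.mark.parametrize("text,expected", [
        ("P1 is driven by P2", "infix"),
        ("Interaction of P1 with P2", "prefix"),
        ("P1 and P2 interact", "postfix"),
    ])
    def test_keyword_position(self, lexicon, text, expected):
        inst = make_instance(text, "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.keyword_position(inst, kw) == expected

    def test_position_none_without_keyword(self, lexicon):
        inst = make_instance("P1 near P2", "P1", "P2")
        assert lf.keyword_position(inst, None) == "none"

    def test_protein_positions_worked_example(self, driven_instance):
        assert lf.protein_positions(driven_instance) == (1, 5)

    def test_protein_positions_are_word_positions(self, lexicon):
        inst = make_instance("a b c P1 d P2", "P1", "P2")
        assert lf.protein_positions(inst) == (4, 6)

    def test_comma_worked_example(self, lexicon, driven_instance):
        kw = lf.select_keyword(driven_instance, lexicon)
        assert lf.comma_feature(driven_instance, kw) == "nn"

    def test_comma_both_gaps(self, lexicon):
        inst = make_instance("P1, which binds stuff, regulates P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert kw.surface == "binds"  # leftmost of the equidistant candidates
        assert lf.comma_feature(inst, kw) == "yy"

    def test_comma_second_gap_only(self, lexicon):
        inst = make_instance("binds P1, P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.comma_feature(inst, kw) == "ny"

    def test_comma_none_without_keyword(self, lexicon):
        inst = make_instance("P1 near P2", "P1", "P2")
        assert lf.comma_feature(inst, None) == "none"


class TestFlags:
    def test_negative_true_conjunctive_false(self, lexicon):
        inst = make_instance("P1 is not driven by P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        neg, conj, which, but, cond = lf.boolean_flags(inst, kw, lexicon)
        assert neg is True and conj is False
        assert which is False and but is False and cond is False

    def test_conjunctive_anywhere_in_sentence(self, lexicon):
        inst = make_instance("P1 binds P2 although weakly", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.boolean_flags(inst, kw, lexicon)[1] is True

    def test_negative_outside_anchors_ignored(self, lexicon):
        inst = make_instance("not that P1 binds P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.boolean_flags(inst, kw, lexicon)[0] is False

    def test_condition_between_anchors(self, lexicon):
        inst = make_instance("P1 binds whether P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.boolean_flags(inst, kw, lexicon)[4] is True


class TestPreposition:
    def test_worked_example(self, lexicon, driven_instance):
        kw = lf.select_keyword(driven_instance, lexicon)
        assert lf.preposition_of_keyword(driven_instance, kw, lexicon) == "by"

    def test_none_when_absent(self, lexicon):
        inst = make_instance("P1 binds P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.preposition_of_keyword(inst, kw, lexicon) == "none"

    def test_distance_boundary_exceeded(self, lexicon):
        # four words between keyword and "with": out of range
        inst = make_instance("P1 binds a b c d with P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.preposition_of_keyword(inst, kw, lexicon) == "none"

    def test_distance_boundary_met(self, lexicon):
        # three words between keyword and "with": in range
        inst = make_instance("P1 binds a b c with P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert lf.preposition_of_keyword(inst, kw, lexicon) == "with"


class TestSecondKeywordsAndParallel:
    def test_selected_keyword_not_second(self, lexicon):
        inst = make_instance("P1 binds P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        multiple, second = lf.multiple_and_second_keywords(inst, kw, lexicon)
        assert multiple is False
        assert all(v is False for v in second.values())

    def test_unselected_second_keyword_between_pair(self, lexicon):
        inst = make_instance("P1 binds and interacts with P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        assert kw.surface == "binds"
        multiple, second = lf.multiple_and_second_keywords(inst, kw, lexicon)
        assert multiple is True
        assert second["interact"] is True
        assert second["bind"] is False

    def test_no_keyword_at_all(self, lexicon):
        inst = make_instance("P1 near P2", "P1", "P2")
        multiple, second = lf.multiple_and_second_keywords(inst, None, lexicon)
        assert multiple is False
        assert not any(second.values())

    @pytest.mark.parametrize("text,p1,p2,expected", [
        ("Protein binds P1 or P2", "P1", "P2", True),
        ("P1 is driven by P2", "P1", "P2", False),
        ("P1 ( P2", "P1", "P2", True),
        ("P1 and P2 interact", "P1", "P2", True),
    ])
    def test_parallel_expression(self, lexicon, text, p1, p2, expected):
        inst = make_instance(text, p1, p2)
        assert lf.parallel_expression(inst) is expected


class TestTotality:
    def test_every_instance_yields_all_44_features(self, lexicon):
        texts = ["P1 and P2", "P1", "xyzzy P1 qwert P2 asdfg",
                 "P1 binds , P2", "binds P1 P2"]
        for text in texts:
            if "P2" in text:
                inst = make_instance(text, "P1", "P2")
                feats = extract_features(inst, lexicon)
                assert set(feats) == set(FEATURE_NAMES)

    def test_infix_distance_identity(self, lexicon):
        # infix keyword: words left of K + words right of K + K = words between pair
        inst = make_instance("P1 aa binds bb cc P2", "P1", "P2")
        kw = lf.select_keyword(inst, lexicon)
        t1, t2, t3 = lf.distance_features(inst, kw)
        assert lf.keyword_position(inst, kw) == "infix"
        assert t1 + t2 + 1 == t3
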