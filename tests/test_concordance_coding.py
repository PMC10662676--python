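"""KWIC extraction, sorting, coding samples, and category extrapolation."""

from fractions import Fraction

import pytest
from conftest import make_post
from hypothesis import given, settings
from hypothesis import strategies as st

from cfa import (
    CodedLine,
    CodingFrame,
    ConcordanceLine,
    Corpus,
    build_frequency_table,
    extract_concordances,
    extrapolate_category_frequencies,
    sample_for_coding,
    sort_concordances,
)
from cfa.corpus_io import NOT_FRAME
from cfa.keyness_analysis import FrequencyTable


class TestExtractConcordances:
    def test_single_occurrence_contexts(self):
        corpus = Corpus([make_post("p1", "alpha beta node gamma delta")])
        (line,) = extract_concordances(corpus, "node", context=20)
        assert line.left == ("alpha", "beta")
        assert line.right == ("gamma", "delta")
        assert (line.start, line.end) == (2, 3)

    def test_node_at_post_start_has_empty_left_context(self):
        corpus = Corpus([make_post("p1", "node gamma")])
        (line,) = extract_concordances(corpus, "node")
        assert line.left == ()
        assert line.right == ("gamma",)

    def test_context_truncated_to_window(self):
        words = [f"w{i}" for i in range(30)] + ["node"] + [f"v{i}" for i in range(30)]
        corpus = Corpus([make_post("p1", " ".join(words))])
        (line,) = extract_concordances(corpus, "node", context=20)
        assert len(line.left) == 20 and len(line.right) == 20
        assert line.left[0] == "w10"

    def test_contexts_skip_punctuation(self):
        corpus = Corpus([make_post("p1", "alpha, beta! node; gamma.")])
        (line,) = extract_concordances(corpus, "node")
        assert line.left == ("alpha", "beta")
        assert line.right == ("gamma",)

    def test_line_count_matches_frequency_table(self, synth_small):
        corpus, truth = synth_small
        table = build_frequency_table(corpus)
        # pick a handful of lemmas across the frequency range
        lemmas = sorted(table.freq, key=table.freq.get)[:: max(1, len(table.freq) // 5)]
        for lemma in lemmas:
            assert len(extract_concordances(corpus, lemma)) == table.freq[lemma]

    def test_absent_lemma_warns_and_returns_empty(self, tiny_corpus):
        with pytest.warns(UserWarning, match="does not occur"):
            assert extract_concordances(tiny_corpus, "zzzmissing") == []


def line(node="node", left=(), right=(), post_id="p", start=0):
    return ConcordanceLine(post_id, node, start, start + 1, tuple(left), tuple(right))


class TestSortConcordances:
    def test_nearest_left_word_sorts_first(self):
        a = line(left=("far", "aaa"), right=("x",))
        b = line(left=("far", "bbb"), right=("x",))
        assert sort_concordances([b, a]) == [a, b]

    def test_right_context_breaks_left_ties(self):
        a = line(left=("same",), right=("aaa",))
        b = line(left=("same",), right=("bbb",))
        assert sort_concordances([b, a]) == [a, b]

    def test_stable_for_identical_keys(self):
        a = line(left=("x",), right=("y",), post_id="first")
        b = line(left=("x",), right=("y",), post_id="second")
        assert sort_concordances([a, b]) == [a, b]
        assert sort_concordances([b, a]) == [b, a]

    def test_permutation_invariance(self):
        import random

        lines = [
            line(left=(f"l{i % 3}", f"m{i % 5}"), right=(f"r{i % 7}",), post_id=str(i))
            for i in range(40)
        ]
        ref = sort_concordances(lines)
        shuffled = lines[:]
        random.Random(9).shuffle(shuffled)
        assert [l.line_id for l in sort_concordances(shuffled)] == [
            l.line_id for l in ref
        ]


class TestSampleForCoding:
    def test_thirty_distinct_lines_sampled(self):
        lines = [line(post_id=str(i), start=i) for i in range(100)]
        sampled = sample_for_coding(lines, n=30, seed=4)
        assert len(sampled) == 30
        assert len({l.line_id for l in sampled}) == 30

    def test_short_supply_returns_all_with_warning(self):
        lines = [line(post_id=str(i), start=i) for i in range(12)]
        with pytest.warns(UserWarning, match="taking all"):
            assert sample_for_coding(lines, n=30, seed=0) == lines

    def test_seed_determinism(self):
        lines = [line(post_id=str(i), start=i) for i in range(100)]
        assert sample_for_coding(lines, 30, seed=8) == sample_for_coding(lines, 30, seed=8)


FRAME = CodingFrame.from_mapping(
    {"D1": ["Relationships", "Work"], "D2": ["Hope"]}
)


def coded(node, labels_per_line):
    return [
        CodedLine(line(node=node, post_id=f"{node}{i}", start=i), frozenset(labels))
        for i, labels in enumerate(labels_per_line)
    ]


def table_for(freqs):
    return FrequencyTable(
        freq=dict(freqs),
        doc_freq={k: 1 for k in freqs},
        user_freq={k: 1 for k in freqs},
        total_tokens=sum(freqs.values()) + 100,
        total_users=10,
        total_posts=10,
    )


class TestExtrapolation:
    def test_proportional_scaling(self):
        labels = [["Relationships"]] * 15 + [["Hope"]] * 15
        result = extrapolate_category_frequencies(
            {"node": coded("node", labels)}, table_for({"node": 300}), FRAME
        )
        assert result.category_mass["Relationships"] == Fraction(150)
        assert result.category_mass["Hope"] == Fraction(150)
        assert result.domain_mass == {"D1": Fraction(150), "D2": Fraction(150)}

    def test_all_lines_outside_frame(self):
        labels = [[NOT_FRAME]] * 10
        result = extrapolate_category_frequencies(
            {"node": coded("node", labels)}, table_for({"node": 500}), FRAME
        )
        assert result.category_mass == {NOT_FRAME: Fraction(500)}
        assert result.domain_mass == {NOT_FRAME: Fraction(500)}

    def test_global_outside_share_reproduces_coded_share(self):
        # 4 lemmas with equal frequency, 16 of 100 coded lines outside
        # the frame -> exactly 16% of the extrapolated mass is outside
        coded_sets = {}
        outside = 16
        for i in range(4):
            take = min(outside, 25)
            outside -= take
            labels = [[NOT_FRAME]] * take + [["Work"]] * (25 - take)
            coded_sets[f"lem{i}"] = coded(f"lem{i}", labels)
        freq = table_for({f"lem{i}": 100 for i in range(4)})
        result = extrapolate_category_frequencies(coded_sets, freq, FRAME)
        assert result.category_mass[NOT_FRAME] / result.total_mass == Fraction(16, 100)

    def test_multi_label_lines_receive_full_mass_per_label(self):
        labels = [["Relationships", "Hope"]] * 10
        result = extrapolate_category_frequencies(
            {"node": coded("node", labels)}, table_for({"node": 100}), FRAME
        )
        assert result.category_mass["Relationships"] == Fraction(100)
        assert result.category_mass["Hope"] == Fraction(100)
        assert result.total_mass == Fraction(200)  # exceeds F under multi-label

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in coding frame"):
            extrapolate_category_frequencies(
                {"node": coded("node", [["Nonsense"]])}, table_for({"node": 10}), FRAME
            )

    def test_empty_coded_set_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="empty coded set"):
            result = extrapolate_category_frequencies(
                {"node": []}, table_for({"node": 10}), FRAME
            )
        assert result.category_mass == {}

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.dictionaries(
            keys=st.sampled_from(["l1", "l2", "l3", "l4"]),
            values=st.tuples(
                st.integers(1, 400),  # corpus frequency
                st.lists(
                    st.sampled_from(["Relationships", "Work", "Hope", NOT_FRAME]),
                    min_size=1, max_size=40,
                ),
            ),
            min_size=1,
        )
    )
    def test_single_label_mass_is_conserved_exactly(self, data):
        coded_sets = {
            lem: coded(lem, [[lab] for lab in labels])
            for lem, (_f, labels) in data.items()
        }
        freq = table_for({lem: f for lem, (f, _l) in data.items()})
        result = extrapolate_category_frequencies(coded_sets, freq, FRAME)
        assert result.total_mass == Fraction(sum(f for f, _l in data.values()))
        assert sum(result.domain_mass.values(), Fraction(0)) == result.total_mass
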