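"""Frequency tables, the G2 keyness statistic, key-lemma selection, and
absent/underused term detection."""

import math

import numpy as np
import pytest
from conftest import make_post
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, chi2_contingency

from cfa import (
    Corpus,
    SynthConfig,
    TermList,
    build_frequency_table,
    find_absent_terms,
    g2_critical_value,
    generate,
    log_likelihood,
    overuse_ratio,
    select_key_lemmas,
)
from cfa.keyness_analysis import FrequencyTable


class TestFrequencyTable:
    def test_single_post_counts(self):
        corpus = Corpus([make_post("p1", "recover recover hope")])
        table = build_frequency_table(corpus)
        assert table.freq == {"recover": 2, "hope": 1}
        assert table.total_tokens == 3
        assert table.doc_freq == {"recover": 1, "hope": 1}

    def test_user_freq_counts_distinct_users(self):
        corpus = Corpus(
            [make_post("p1", "hope", user_id="u1"), make_post("p2", "hope", user_id="u2")]
        )
        table = build_frequency_table(corpus)
        assert table.user_freq["hope"] == 2
        assert table.total_users == 2

    def test_counts_match_brute_force_token_scan(self, synth_small):
        corpus, _ = synth_small
        table = build_frequency_table(corpus)
        # independent recount straight over the token layer
        naive: dict[str, int] = {}
        total = 0
        for seq in corpus.tokens().values():
            for t in seq:
                if t.is_word:
                    naive[t.lemma] = naive.get(t.lemma, 0) + 1
                    total += 1
        assert table.freq == naive
        assert table.total_tokens == total
        assert sum(table.freq.values()) == table.total_tokens
        for lem in table.freq:
            assert table.freq[lem] >= table.doc_freq[lem] >= 1
            assert table.user_freq[lem] <= table.doc_freq[lem]

    def test_empty_corpus_is_hard_error(self):
        with pytest.raises(ValueError):
            build_frequency_table(Corpus([]))


class TestLogLikelihood:
    def test_equal_relative_frequencies_give_zero(self):
        assert log_likelihood(10, 20, 1000, 2000) == 0.0

    def test_worked_example(self):
        # full 2x2 table [[30, 9970], [10, 9990]]: G2 = 2*sum O*ln(O/E)
        n, k = 20000, 40
        expected = 2 * sum(
            o * math.log(o * n / (row * col))
            for o, row, col in [
                (30, 10000, k), (9970, 10000, n - k),
                (10, 10000, k), (9990, 10000, n - k),
            ]
        )
        got = log_likelihood(30, 10, 10000, 10000)
        assert got == pytest.approx(expected, abs=1e-12)
        # the familiar two-cell shorthand is a close rare-word approximation
        shorthand = 2 * (30 * math.log(1.5) + 10 * math.log(0.5))
        assert shorthand == pytest.approx(10.4652, abs=1e-3)
        assert got == pytest.approx(shorthand, abs=0.05)

    def test_zero_reference_cell_positive_and_increasing(self):
        values = [log_likelihood(a, 0, 1000, 1000) for a in (1, 5, 20)]
        assert values[0] > 0
        assert values == sorted(values)

    def test_symmetric_under_corpus_swap(self):
        assert log_likelihood(7, 3, 500, 900) == pytest.approx(
            log_likelihood(3, 7, 900, 500), abs=1e-12
        )

    @pytest.mark.parametrize(
        "args", [(1, 1, 0, 10), (0, 0, 10, 10), (11, 0, 10, 10), (-1, 2, 10, 10)]
    )
    def test_preconditions_enforced(self, args):
        with pytest.raises(ValueError):
            log_likelihood(*args)

    def test_agrees_with_four_cell_contingency_g_test(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            c, d = rng.integers(10, 10_000, size=2)
            a = int(rng.integers(0, c))
            b = int(rng.integers(0, d))
            if a + b == 0 or a == c or b == d:
                continue
            res = chi2_contingency(
                [[a, c - a], [b, d - b]], correction=False, lambda_="log-likelihood"
            )
            assert log_likelihood(a, b, c, d) == pytest.approx(res.statistic, abs=1e-9)

    def test_minimized_at_proportional_counts(self):
        c, d, total = 1000, 3000, 40
        base = round(total * c / (c + d))  # proportional allocation a = 10

        def g_at(a):
            return log_likelihood(a, total - a, c, d)

        up = [g_at(a) for a in range(base, total + 1)]
        down = [g_at(a) for a in range(base, -1, -1)]
        assert up == sorted(up)
        assert down == sorted(down)


class TestOveruseRatio:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((30, 10, 10000, 10000), 3.0),
            ((10, 10, 1000, 1000), 1.0),
            ((5, 0, 1000, 2000), 20.0),  # (5/1000)/(0.5/2000)
            ((0, 5, 1000, 1000), 0.0),
        ],
    )
    def test_examples(self, args, expected):
        assert overuse_ratio(*args) == pytest.approx(expected, abs=1e-12)


class TestCriticalValue:
    def test_matches_chi_square_one_df_quantile(self):
        gate = g2_critical_value(1e-4)
        assert gate == pytest.approx(chi2.isf(1e-4, 1), abs=1e-12)
        assert 15.0 < gate < 15.2


class TestSelectKeyLemmas:
    @staticmethod
    def table(freq, user_freq, tokens, users, doc_freq=None):
        return FrequencyTable(
            freq=dict(freq),
            doc_freq=doc_freq or {k: 1 for k in freq},
            user_freq=dict(user_freq),
            total_tokens=tokens,
            total_users=users,
            total_posts=10,
        )

    def test_ratio_below_two_is_never_key(self):
        target = self.table({"x": 150}, {"x": 50}, 10_000, 100)
        reference = self.table({"x": 100}, {"x": 50}, 10_000, 100)
        (res,) = select_key_lemmas(target, reference)
        assert res.ratio == pytest.approx(1.5)
        assert not res.is_key

    def test_low_user_share_fails_dispersion_gate(self):
        target = self.table({"x": 400}, {"x": 2}, 10_000, 100)
        reference = self.table({"x": 100}, {"x": 50}, 10_000, 100)
        (res,) = select_key_lemmas(target, reference)
        assert res.ratio >= 4 and res.g2 > 30
        assert res.user_share == pytest.approx(0.02)
        assert not res.is_key

    def test_flag_invariant_holds_row_by_row(self, synth_small):
        corpus, truth = synth_small
        target = corpus.subset([p for p in corpus if p.post_id in truth.relevant_posts], "t")
        reference = corpus.subset([p for p in corpus if p.post_id not in truth.relevant_posts], "r")
        results = select_key_lemmas(
            build_frequency_table(target), build_frequency_table(reference)
        )
        gate = g2_critical_value(1e-4)
        for r in results:
            recheck = (
                r.a * r.d > r.b * r.c
                and r.ratio >= 2.0
                and r.g2 >= gate
                and r.user_share >= 0.05
            )
            assert r.is_key == recheck
        g2s = [r.g2 for r in results]
        assert g2s == sorted(g2s, reverse=True)

    def test_planted_lemmas_recovered_from_enriched_corpus(self):
        corpus, truth = generate(SynthConfig(seed=5, planted_collocations=()))
        target = corpus.subset([p for p in corpus if p.post_id in truth.relevant_posts], "t")
        reference = corpus.subset([p for p in corpus if p.post_id not in truth.relevant_posts], "r")
        results = select_key_lemmas(
            build_frequency_table(target), build_frequency_table(reference)
        )
        key = {r.lemma for r in results if r.is_key}
        planted = truth.planted_lemmas
        assert len(key & planted) / len(planted) >= 0.9
        assert len(key & planted) / max(1, len(key)) >= 0.9


class TestAbsentTerms:
    def test_missing_and_underused_classification(self):
        corpus_t = Corpus([make_post("p1", " ".join(["hope"] * 2 + ["filler"] * 98))])
        corpus_r = Corpus([make_post("p2", " ".join(["hope"] * 6 + ["filler"] * 94))])
        terms = TermList([("hope",), ("gone",)])
        target = build_frequency_table(corpus_t, terms)
        reference = build_frequency_table(corpus_r, terms)
        missing, underused = find_absent_terms(terms, target, reference)
        assert missing == ["gone"]       # 0 frequency in target
        assert underused == ["hope"]     # 2/100 < 6/100
        assert not set(missing) & set(underused)

    def test_equal_relative_frequency_is_neither(self):
        corpus_t = Corpus([make_post("p1", "hope filler filler filler")])
        corpus_r = Corpus([make_post("p2", "hope filler filler filler")])
        terms = TermList([("hope",)])
        missing, underused = find_absent_terms(
            terms,
            build_frequency_table(corpus_t, terms),
            build_frequency_table(corpus_r, terms),
        )
        assert missing == [] and underused == []

    def test_multiword_terms_use_span_counts(self):
        corpus_t = Corpus([make_post("p1", "care and more care here")])
        corpus_r = Corpus([make_post("p2", "take care of it take care")])
        terms = TermList([("take", "care")])
        missing, underused = find_absent_terms(
            terms,
            build_frequency_table(corpus_t, terms),
            build_frequency_table(corpus_r, terms),
        )
        assert missing == ["take care"]

    def test_tables_must_carry_term_counts(self):
        corpus = Corpus([make_post("p1", "hope")])
        terms = TermList([("hope",)])
        bare = build_frequency_table(corpus)
        with pytest.raises(ValueError, match="term counts"):
            find_absent_terms(terms, bare, bare)


@settings(max_examples=100, deadline=None)
@given(
    a=st.integers(0, 500),
    b=st.integers(0, 500),
    c=st.integers(501, 5000),
    d=st.integers(501, 5000),
)
def test_g2_nonnegative_and_zero_iff_proportional(a, b, c, d):
    if a + b == 0:
        return
    g2 = log_likelihood(a, b, c, d)
    assert g2 >= 0.0
    if a * d == b * c:
        assert g2 == pytest.approx(0.0, abs=1e-9)
    elif g2 == 0.0:
        assert a * d == b * c
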