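"""Contrastive keyness statistics.

A lemma is *key* in the target corpus relative to the reference corpus
when it clears three gates jointly:

* significance — the log-likelihood (G2) statistic, i.e. the
  likelihood-ratio G for the 2x2 contingency table

      [[a, c - a], [b, d - b]],   G2 = 2 * sum_cells O * ln(O / E),

  with ``a``/``b`` the lemma's frequencies, ``c``/``d`` the word totals
  of target and reference, expected counts from the table margins, and
  the convention O*ln(O/E) := 0 at O = 0 (no smoothing).  For rare
  lemmas this coincides with the familiar two-cell shorthand
  2*(a*ln(a/E1) + b*ln(b/E2)).  A lemma is significant when G2 exceeds
  the chi-square(1) upper quantile at alpha = 1e-4 (about 15.13,
  derived at call time, never hard-coded);
* effect size — the relative-frequency ratio (a/c)/(b/d) is at least 2
  ("overused at least twice"), with the zero reference cell smoothed as
  b := 0.5 for the ratio only (G2 itself uses the 0*ln0 = 0 convention,
  no smoothing);
* dispersion — the lemma is used by at least 5% of target-corpus users,
  guarding against one prolific author driving keyness.

Underuse of concept terms is reported separately: *missing* terms have
zero target frequency; *underused* terms occur but at a lower relative
frequency than in the reference corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus_io import Corpus, TermList
from .text_processing import match_terms

__all__ = [
    "FrequencyTable",
    "KeynessResult",
    "build_frequency_table",
    "log_likelihood",
    "overuse_ratio",
    "g2_critical_value",
    "select_key_lemmas",
    "find_absent_terms",
]


@dataclass
class FrequencyTable:
    """Per-lemma occurrence, document and distinct-user frequencies.

    ``total_tokens`` is the corpus word-token count C (the sum of all
    per-lemma frequencies); ``total_users`` the distinct-author count.
    When built with a term list, ``term_freq`` additionally holds
    match-span counts per term string, which is how multiword concept
    terms get a frequency.
    """

    freq: dict[str, int]
    doc_freq: dict[str, int]
    user_freq: dict[str, int]
    total_tokens: int
    total_users: int
    total_posts: int
    name: str = "corpus"
    term_freq: dict[str, int] = field(default_factory=dict)

    def rel_freq(self, lemma: str) -> float:
        return self.freq.get(lemma, 0) / self.total_tokens

    def __eq__(self, other) -> bool:
        return isinstance(other, FrequencyTable) and (
            self.freq == other.freq
            and self.doc_freq == other.doc_freq
            and self.user_freq == other.user_freq
            and self.total_tokens == other.total_tokens
            and self.total_users == other.total_users
            and self.total_posts == other.total_posts
            and self.term_freq == other.term_freq
        )


def build_frequency_table(
    corpus: Corpus, terms: TermList | None = None, analyzer=None
) -> FrequencyTable:
    """Count lemma frequencies over the word tokens of a corpus."""
    if not len(corpus):
        raise ValueError("cannot build a frequency table for an empty corpus")
    tokens = corpus.tokens(analyzer)
    freq: dict[str, int] = {}
    doc_freq: dict[str, int] = {}
    user_seen: dict[str, set[str]] = {}
    total = 0
    for post in corpus:
        seen_here: set[str] = set()
        for t in tokens[post.post_id]:
            if not t.is_word:
                continue
            total += 1
            lem = t.lemma
            freq[lem] = freq.get(lem, 0) + 1
            seen_here.add(lem)
        uid = post.user_id
        for lem in seen_here:
            doc_freq[lem] = doc_freq.get(lem, 0) + 1
            user_seen.setdefault(lem, set()).add(uid)
    user_freq = {lem: len(u) for lem, u in user_seen.items()}

    term_freq: dict[str, int] = {}
    if terms is not None:
        term_freq = {" ".join(t): 0 for t in terms}
        for post in corpus:
            for term, _s, _e in match_terms(tokens[post.post_id], terms):
                term_freq[" ".join(term)] += 1

    return FrequencyTable(
        freq=freq,
        doc_freq=doc_freq,
        user_freq=user_freq,
        total_tokens=total,
        total_users=corpus.user_count,
        total_posts=len(corpus),
        name=corpus.name,
        term_freq=term_freq,
    )


def _check_cells(a: float, b: float, c: float, d: float) -> None:
    if c <= 0 or d <= 0:
        raise ValueError("corpus sizes c and d must be positive")
    if a + b < 1:
        raise ValueError("lemma must occur at least once overall (a + b >= 1)")
    if a < 0 or b < 0 or a > c or b > d:
        raise ValueError("require 0 <= a <= c and 0 <= b <= d")


def log_likelihood(a: float, b: float, c: float, d: float) -> float:
    """Log-likelihood (G2) keyness statistic.

    The likelihood-ratio G for the 2x2 table [[a, c-a], [b, d-b]]:
    symmetric under swapping (a, c) <-> (b, d); zero exactly when the
    relative frequencies a/c and b/d coincide.
    """
    _check_cells(a, b, c, d)
    n = c + d
    k = a + b  # column total for the lemma
    g2 = 0.0
    for o, row, col in ((a, c, k), (c - a, c, n - k), (b, d, k), (d - b, d, n - k)):
        if o > 0:
            g2 += o * math.log(o * n / (row * col))
    return max(0.0, 2.0 * g2)


def _g2_array(a: np.ndarray, b: np.ndarray, c: float, d: float) -> np.ndarray:
    """Vectorized G2 over per-lemma count arrays (same convention)."""
    n = c + d
    k = a + b
    out = np.zeros_like(a, dtype=float)
    for o, row, col in ((a, c, k), (c - a, c, n - k), (b, d, k), (d - b, d, n - k)):
        ratio = o * n / (row * np.where(col > 0, col, 1.0))
        out += np.where(o > 0, o * np.log(np.where(o > 0, ratio, 1.0)), 0.0)
    return np.maximum(0.0, 2.0 * out)


def overuse_ratio(a: float, b: float, c: float, d: float) -> float:
    """Relative-frequency ratio (a/c) / (b/d).

    A zero reference cell is smoothed additively (b := 0.5) for this
    ratio only, so a lemma absent from the reference still gets a
    finite effect size; a zero target cell yields ratio 0 (such a lemma
    can never be key).
    """
    _check_cells(a, b, c, d)
    if a == 0:
        return 0.0
    b_eff = b if b > 0 else 0.5
    return (a / c) / (b_eff / d)


def g2_critical_value(alpha: float = 1e-4) -> float:
    """G2 gate: the chi-square(1) upper quantile at ``alpha``."""
    return float(stats.chi2.isf(alpha, df=1))


@dataclass(frozen=True)
class KeynessResult:
    """Contrastive statistics for one lemma.

    ``is_key`` is exactly the conjunction: overused in target
    (a/c > b/d), ratio >= min_ratio, G2 >= the alpha gate, and used by
    at least ``min_user_share`` of target-corpus users.
    """

    lemma: str
    a: int
    b: int
    c: int
    d: int
    ratio: float
    g2: float
    significant: bool
    user_share: float
    is_key: bool

    _FIELDS = ("lemma", "a", "b", "c", "d", "ratio", "g2", "significant",
               "user_share", "is_key")

    def to_row(self) -> dict[str, str]:
        return {
            "lemma": self.lemma,
            "a": str(self.a), "b": str(self.b),
            "c": str(self.c), "d": str(self.d),
            "ratio": repr(self.ratio), "g2": repr(self.g2),
            "significant": str(int(self.significant)),
            "user_share": repr(self.user_share),
            "is_key": str(int(self.is_key)),
        }

    @classmethod
    def from_row(cls, row: Mapping[str, str]) -> "KeynessResult":
        return cls(
            lemma=row["lemma"],
            a=int(row["a"]), b=int(row["b"]), c=int(row["c"]), d=int(row["d"]),
            ratio=float(row["ratio"]), g2=float(row["g2"]),
            significant=bool(int(row["significant"])),
            user_share=float(row["user_share"]),
            is_key=bool(int(row["is_key"])),
        )


def select_key_lemmas(
    target: FrequencyTable,
    reference: FrequencyTable,
    alpha: float = 1e-4,
    min_ratio: float = 2.0,
    min_user_share: float = 0.05,
) -> list[KeynessResult]:
    """Score every lemma in the union vocabulary and flag the key ones.

    Results are sorted by G2 descending, ties broken by lemma.  The
    dispersion denominator is the *target* corpus user count.
    """
    c = target.total_tokens
    d = reference.total_tokens
    gate = g2_critical_value(alpha)
    vocab = sorted(set(target.freq) | set(reference.freq))
    a_arr = np.array([target.freq.get(l, 0) for l in vocab], dtype=float)
    b_arr = np.array([reference.freq.get(l, 0) for l in vocab], dtype=float)
    g2_arr = _g2_array(a_arr, b_arr, float(c), float(d))

    results: list[KeynessResult] = []
    for lemma, a, b, g2 in zip(vocab, a_arr, b_arr, g2_arr):
        a = int(a)
        b = int(b)
        ratio = overuse_ratio(a, b, c, d)
        share = target.user_freq.get(lemma, 0) / target.total_users
        significant = g2 >= gate
        overused = a * d > b * c  # a/c > b/d without division
        is_key = overused and ratio >= min_ratio and significant and share >= min_user_share
        results.append(
            KeynessResult(lemma, a, b, c, d, ratio, float(g2), bool(significant),
                          share, bool(is_key))
        )
    results.sort(key=lambda r: (-r.g2, r.lemma))
    return results


def find_absent_terms(
    terms: TermList, target: FrequencyTable, reference: FrequencyTable
) -> tuple[list[str], list[str]]:
    """Concept terms missing from or underused in the target corpus.

    Both tables must have been built with ``terms`` so multiword term
    frequencies (match-span counts) are available.  Returns
    ``(missing, underused)``: missing terms have target frequency 0;
    underused terms occur in the target but at a strictly lower relative
    frequency than in the reference.  The lists are disjoint.
    """
    for tbl in (target, reference):
        for s in (" ".join(t) for t in terms):
            if s not in tbl.term_freq:
                raise ValueError(
                    f"table {tbl.name!r} lacks term counts for {s!r}; "
                    "build_frequency_table must be called with the term list"
                )
    missing: list[str] = []
    underused: list[str] = []
    for term in terms.strings():
        ft = target.term_freq[term]
        fr = reference.term_freq[term]
        if ft == 0:
            missing.append(term)
        elif ft * reference.total_tokens < fr * target.total_tokens:
            underused.append(term)
    return missing, underused


# --------------------------------------------------------------------------
# Frequency-table / keyness-table serialization helpers
# --------------------------------------------------------------------------

def frequency_table_rows(table: FrequencyTable) -> list[dict[str, str]]:
    rows = [
        {
            "lemma": lem,
            "freq": str(table.freq[lem]),
            "doc_freq": str(table.doc_freq[lem]),
            "user_freq": str(table.user_freq[lem]),
        }
        for lem in sorted(table.freq)
    ]
    return rows


def frequency_table_metadata(table: FrequencyTable) -> dict[str, str]:
    md = {
        "corpus": table.name,
        "total_tokens": str(table.total_tokens),
        "total_users": str(table.total_users),
        "total_posts": str(table.total_posts),
    }
    if table.term_freq:
        md["term_freq"] = ";".join(
            f"{t}={n}" for t, n in sorted(table.term_freq.items())
        )
    return md


def frequency_table_from_rows(
    rows: Sequence[Mapping[str, str]], metadata: Mapping[str, str]
) -> FrequencyTable:
    freq = {r["lemma"]: int(r["freq"]) for r in rows}
    doc_freq = {r["lemma"]: int(r["doc_freq"]) for r in rows}
    user_freq = {r["lemma"]: int(r["user_freq"]) for r in rows}
    term_freq: dict[str, int] = {}
    if metadata.get("term_freq"):
        for item in metadata["term_freq"].split(";"):
            t, _, n = item.rpartition("=")
            term_freq[t] = int(n)
    return FrequencyTable(
        freq=freq,
        doc_freq=doc_freq,
        user_freq=user_freq,
        total_tokens=int(metadata["total_tokens"]),
        total_users=int(metadata["total_users"]),
        total_posts=int(metadata["total_posts"]),
        name=metadata.get("corpus", "corpus"),
        term_freq=term_freq,
    )
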