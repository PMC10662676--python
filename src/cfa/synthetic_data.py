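"""Synthetic forum-corpus generator with known ground truth.

Real self-reported-diagnosis forum datasets are access-restricted, so
every pipeline stage is exercised on generated corpora instead: posts
are bags of pseudo-word lemmas drawn from a Zipfian background
vocabulary plus a closed function-word set, rendered as sentences.  The
generator plants every signal the pipeline is supposed to recover:

* a *relevant* subset of posts in which concept terms (single words and
  multiword phrases) appear at ``enrichment`` times their base rate;
* *self-reporter* users who receive one first-person diagnosis sentence
  ("i was diagnosed with bipolar ...") in one of their posts;
* per-post *condition mentions* at a configured rate;
* *collocation pairs* whose collocate is inserted within five word
  positions of its node at a configured rate.

Pseudo-lemmas are built from open syllables (consonant+vowel), so they
are fixed points of the default lemmatizer, and their suffixes encode a
coarse POS (plain = noun, -ate = verb, -ous = adjective, -ly = adverb)
so the collocation content-word filter is exercised.  Generation is
fully deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .corpus_io import Corpus, Post, TermList

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate",
    "default_planted_terms",
    "fit_zipf_exponent",
]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]  # 70 open syllables

_FUNCTION_WORDS = (
    "the and i to of a in it you that for on with my this but not so at be have".split()
)

_EVIDENCE_SENTENCE = ("i", "was", "diagnosed", "with", "bipolar", "last", "year")


def _pseudo_word(index: int, n_syllables: int = 3, prefix: str = "") -> str:
    parts = []
    x = index
    for _ in range(n_syllables):
        parts.append(_SYLLABLES[x % len(_SYLLABLES)])
        x //= len(_SYLLABLES)
    return prefix + "".join(parts)


def _background_vocab(size: int) -> tuple[list[str], list[str]]:
    """Deterministic pseudo-lemma vocabulary with POS-encoding suffixes."""
    lemmas: list[str] = []
    pos: list[str] = []
    for i in range(size):
        base = _pseudo_word(i)
        slot = i % 10
        if slot < 6:
            lemmas.append(base)
            pos.append("NOUN")
        elif slot < 8:
            lemmas.append(base + "te")  # vowel-final base -> "...ate"-like VERB cue
            pos.append("VERB" if base.endswith("a") else "NOUN")
        elif slot < 9:
            lemmas.append(base + "us")
            pos.append("ADJ" if base.endswith("o") else "NOUN")
        else:
            lemmas.append(base + "ly")
            pos.append("ADV")
    return lemmas, pos


def default_planted_terms(n_single: int = 16, n_multi: int = 4) -> TermList:
    """Dedicated concept-term inventory (``pr``-prefixed pseudo-lemmas)."""
    terms: list[tuple[str, ...]] = []
    for i in range(n_single):
        terms.append((_pseudo_word(i, prefix="pr"),))
    for i in range(n_multi):
        terms.append(
            (_pseudo_word(n_single + 2 * i, prefix="pr"),
             _pseudo_word(n_single + 2 * i + 1, prefix="pr"))
        )
    return TermList(terms)


def _default_collocations() -> tuple[tuple[str, str, float], ...]:
    # nodes are the first two planted single-word terms; collocates are
    # dedicated "cl"-prefixed lemmas that occur only via planting
    return (
        (_pseudo_word(0, prefix="pr"), _pseudo_word(0, prefix="cl"), 0.5),
        (_pseudo_word(1, prefix="pr"), _pseudo_word(1, prefix="cl"), 0.5),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus.

    ``planted_term_base_rate`` is the per-word-slot probability of each
    planted term in a background post; relevant posts multiply the total
    planted rate by ``enrichment``.
    """

    seed: int = 0
    n_users: int = 200
    posts_per_user: tuple[int, int] = (5, 15)
    words_per_post: tuple[int, int] = (50, 150)
    vocab_size: int = 5000
    zipf_exponent: float = 1.1
    relevant_fraction: float = 0.2
    planted_terms: TermList | None = None  # default: 16 single + 4 bigram terms
    planted_term_base_rate: float = 0.002
    enrichment: float = 4.0
    self_report_fraction: float = 0.1
    condition_term: str = "bipolar"
    condition_mention_rate: float = 0.4
    planted_collocations: tuple[tuple[str, str, float], ...] = _default_collocations()
    subforum_names: tuple[str, ...] = ("bipolar", "bipolarreddit", "mentalhealth", "offtopic")
    subforum_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    function_word_rate: float = 0.25
    title_fraction: float = 0.2

    def resolved_terms(self) -> TermList:
        return self.planted_terms or default_planted_terms()

    def validate(self) -> None:
        for name in ("relevant_fraction", "self_report_fraction",
                     "condition_mention_rate", "function_word_rate", "title_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        terms = self.resolved_terms()
        if self.vocab_size < len(terms):
            raise ValueError("vocab_size must be >= number of planted terms")
        max_len = max(len(t) for t in terms)
        if self.words_per_post[0] < max_len:
            raise ValueError(
                "words_per_post lower bound is smaller than the longest planted term"
            )
        total_rate = self.planted_term_base_rate * len(terms) * self.enrichment
        if total_rate + self.function_word_rate >= 1.0:
            raise ValueError("planted + function word rates exceed 1 per slot")
        if len(self.subforum_probs) != len(self.subforum_names):
            raise ValueError("subforum_probs must match subforum_names")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery experiments."""

    relevant_posts: set[str]
    self_reporters: set[str]
    planted_terms: list[str]
    planted_lemmas: set[str]
    condition_posts: set[str]
    planted_pairs: list[tuple[str, str]]
    background_vocab: tuple[str, ...] = field(default_factory=tuple)


def generate(config: SynthConfig = SynthConfig()) -> tuple[Corpus, GroundTruth]:
    """Generate a user-attributed corpus and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    terms = config.resolved_terms()
    term_words = [list(t) for t in terms]
    n_terms = len(term_words)

    vocab, _vocab_pos = _background_vocab(config.vocab_size)
    vocab_arr = np.array(vocab, dtype=object)
    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    probs = ranks ** (-config.zipf_exponent)
    probs /= probs.sum()
    cdf = np.cumsum(probs)

    func_arr = np.array(_FUNCTION_WORDS, dtype=object)
    colloc = [(str(n), str(c), float(r)) for n, c, r in config.planted_collocations]

    posts: list[Post] = []
    relevant_posts: set[str] = set()
    self_reporters: set[str] = set()
    condition_posts: set[str] = set()

    base_total = config.planted_term_base_rate * n_terms
    post_counter = 0
    minute = 0

    for u in range(config.n_users):
        user_id = f"u{u:05d}"
        is_reporter = rng.random() < config.self_report_fraction
        if is_reporter:
            self_reporters.add(user_id)
        n_posts = int(rng.integers(config.posts_per_user[0], config.posts_per_user[1] + 1))
        evidence_at = int(rng.integers(n_posts)) if is_reporter else -1

        for k in range(n_posts):
            post_id = f"p{post_counter:07d}"
            post_counter += 1
            is_relevant = rng.random() < config.relevant_fraction
            p_term = base_total * (config.enrichment if is_relevant else 1.0)

            n_words = int(rng.integers(config.words_per_post[0], config.words_per_post[1] + 1))
            u_draw = rng.random(n_words)
            is_term = u_draw < p_term
            is_func = (~is_term) & (u_draw < p_term + config.function_word_rate)
            n_bg = int((~is_term & ~is_func).sum())
            bg_idx = np.searchsorted(cdf, rng.random(n_bg))
            bg_words = vocab_arr[bg_idx]
            term_ids = rng.integers(0, n_terms, size=int(is_term.sum()))
            func_ids = rng.integers(0, len(func_arr), size=int(is_func.sum()))

            # groups: multiword terms stay atomic so sentence breaks and
            # collocate insertions never split them
            groups: list[list[str]] = []
            ti = fi = bi = 0
            for slot in range(n_words):
                if is_term[slot]:
                    groups.append(list(term_words[term_ids[ti]]))
                    ti += 1
                elif is_func[slot]:
                    groups.append([str(func_arr[func_ids[fi]])])
                    fi += 1
                else:
                    groups.append([str(bg_words[bi])])
                    bi += 1

            # condition mention
            if rng.random() < config.condition_mention_rate:
                pos = int(rng.integers(len(groups) + 1))
                groups.insert(pos, [config.condition_term])

            # planted collocates near node occurrences
            for node, coll, rate in colloc:
                insertions = []
                for gi, g in enumerate(groups):
                    if node in g and rng.random() < rate:
                        offset = int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
                        insertions.append((max(0, min(len(groups), gi + offset)), coll))
                for pos, coll_word in sorted(insertions, reverse=True):
                    groups.insert(pos, [coll_word])

            # self-report evidence sentence leads its post
            if k == evidence_at:
                groups.insert(0, list(_EVIDENCE_SENTENCE))

            # render: sentence break every 8-16 groups
            words: list[str] = []
            until_break = int(rng.integers(8, 17))
            for g in groups:
                words.extend(g)
                until_break -= 1
                if until_break == 0:
                    words.append(".")
                    until_break = int(rng.integers(8, 17))
            body = " ".join(words).replace(" .", ".") + "."

            if rng.random() < config.title_fraction:
                t_idx = np.searchsorted(cdf, rng.random(int(rng.integers(3, 7))))
                title = " ".join(str(w) for w in vocab_arr[t_idx])
            else:
                title = ""

            subforum = str(rng.choice(np.array(config.subforum_names, dtype=object),
                                      p=np.array(config.subforum_probs)))
            created = f"2019-01-01T{(minute // 60) % 24:02d}:{minute % 60:02d}:00Z"
            minute += 1

            if is_relevant:
                relevant_posts.add(post_id)
            if config.condition_term in words:
                condition_posts.add(post_id)

            posts.append(Post(post_id, user_id, subforum, created, title, body))

    truth = GroundTruth(
        relevant_posts=relevant_posts,
        self_reporters=self_reporters,
        planted_terms=terms.strings(),
        planted_lemmas={lem for t in terms for lem in t},
        condition_posts=condition_posts,
        planted_pairs=[(n, c) for n, c, _r in colloc],
        background_vocab=tuple(vocab),
    )
    return Corpus(posts, name=f"synthetic-{config.seed}"), truth


def fit_zipf_exponent(counts: Sequence[int], vocab_size: int | None = None) -> float:
    """Maximum-likelihood Zipf exponent from background lemma counts.

    ``counts`` are per-lemma occurrence counts (any order); the model is
    p(rank r) proportional to r**(-s) over a bounded vocabulary.
    """
    c = np.sort(np.asarray(counts, dtype=float))[::-1]
    c = c[c > 0]
    if vocab_size is None:
        vocab_size = len(c)
    ranks = np.arange(1, len(c) + 1, dtype=float)
    all_ranks = np.arange(1, vocab_size + 1, dtype=float)
    n = c.sum()
    log_ranks = np.log(ranks)

    def nll(s: float) -> float:
        return s * float(c @ log_ranks) + n * np.log(np.sum(all_ranks ** (-s)))

    res = minimize_scalar(nll, bounds=(0.05, 4.0), method="bounded")
    return float(res.x)
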