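"""Concept-relevance scoring and corpus splitting.

Every post is scored by TF-IDF-weighted cosine similarity between its
term-list profile and the term list itself (the "query"): the post
vector holds tf(term, post) x idf(term) over term-list entries, the
query vector holds the idf weights, and the score is the cosine of the
two.  Multiword terms are counted through the greedy longest-match
term matcher, idf uses the smoothed form ln((1+N)/(1+df)) + 1 computed
over the scored corpus, and scores live in [0, 1] with 0 exactly when a
post shares no term with the list.

The scored posts are then split into a high-relevance target corpus and
a low-relevance reference corpus by strict score cutoffs plus a minimum
word-length gate; decile sampling supports the human calibration coding
that chooses those cutoffs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .corpus_io import Corpus, TermList
from .text_processing import match_terms

__all__ = [
    "RelevanceScore",
    "SplitConfig",
    "score_relevance",
    "decile_sample",
    "split_corpus",
]

logger = logging.getLogger(__name__)


class RelevanceScore(NamedTuple):
    post_id: str
    score: float


@dataclass(frozen=True)
class SplitConfig:
    """Cutoffs and length gate for the target/reference split.

    "Above"/"below" are strict inequalities; posts scoring inside
    ``[lower_cutoff, upper_cutoff]`` belong to neither corpus, and posts
    shorter than ``min_words`` words to neither either.
    """

    upper_cutoff: float = 0.025
    lower_cutoff: float = 0.013
    min_words: int = 94

    def __post_init__(self):
        if not (0 <= self.lower_cutoff < self.upper_cutoff):
            raise ValueError("require 0 <= lower_cutoff < upper_cutoff")


def score_relevance(
    corpus: Corpus, terms: TermList, analyzer=None, idf_corpus: Corpus | None = None
) -> list[RelevanceScore]:
    """TF-IDF cosine similarity of every post to the term list.

    ``idf_corpus`` optionally supplies the document-frequency statistics
    (defaults to the scored corpus itself).
    """
    if not len(corpus):
        raise ValueError("cannot score an empty corpus")
    term_tuples = list(terms.terms)
    t_index = {t: i for i, t in enumerate(term_tuples)}
    k = len(term_tuples)

    def term_counts(c: Corpus) -> dict[str, np.ndarray]:
        tokens = c.tokens(analyzer)
        out = {}
        for p in c:
            tf = np.zeros(k)
            for term, _s, _e in match_terms(tokens[p.post_id], terms):
                tf[t_index[term]] += 1
            out[p.post_id] = tf
        return out

    tf_by_post = term_counts(corpus)
    if idf_corpus is None or idf_corpus is corpus:
        df_counts = tf_by_post.values()
        n_docs = len(corpus)
    else:
        df_counts = term_counts(idf_corpus).values()
        n_docs = len(idf_corpus)
    df = np.zeros(k)
    for tf in df_counts:
        df += tf > 0
    unseen = int((df == 0).sum())
    if unseen:
        logger.info("%d term(s) occur in no document; they contribute 0 to every score", unseen)
    idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0

    query = idf
    qnorm = float(np.linalg.norm(query))
    scores = []
    for p in corpus:
        vec = tf_by_post[p.post_id] * idf
        norm = float(np.linalg.norm(vec))
        if norm == 0.0 or qnorm == 0.0:
            scores.append(RelevanceScore(p.post_id, 0.0))
        else:
            cos = float(vec @ query) / (norm * qnorm)
            scores.append(RelevanceScore(p.post_id, min(1.0, max(0.0, cos))))
    return scores


def decile_sample(
    scores: Sequence[RelevanceScore], per_decile: int, seed: int
) -> list[str]:
    """Sample post ids from every 10%-quantile bin of the scores.

    Scores are sorted ascending and partitioned into 10 equal-count
    bins.  Consecutive bins whose scores are all identical (for example
    a zero-inflated bottom) are merged and contribute ``per_decile``
    ids in total, matching a calibration design that takes only one
    bin's worth of posts from a run of all-equal quantiles.  Sampling is
    uniform without replacement and deterministic under the seed.
    """
    if per_decile < 1:
        raise ValueError("per_decile must be >= 1")
    if not scores:
        return []
    ordered = sorted(scores, key=lambda s: (s.score, s.post_id))
    bins = [list(b) for b in np.array_split(np.arange(len(ordered)), 10) if len(b)]

    # merge adjacent bins that jointly hold a single distinct score value
    groups: list[list[int]] = []
    group_vals: list[set[float]] = []
    for b in bins:
        vals = {ordered[i].score for i in b}
        if groups and len(vals) == 1 and group_vals[-1] == vals:
            groups[-1].extend(b)
        else:
            groups.append(list(b))
            group_vals.append(vals)

    rng = np.random.default_rng(seed)
    sampled: list[str] = []
    for g in groups:
        ids = [ordered[i].post_id for i in g]
        if len(ids) < per_decile:
            warnings.warn(
                f"quantile bin holds only {len(ids)} posts (< {per_decile}); taking all",
                stacklevel=2,
            )
            take = ids
        else:
            take = [str(x) for x in rng.choice(ids, size=per_decile, replace=False)]
        sampled.extend(take)
    return sampled


def split_corpus(
    corpus: Corpus,
    scores: Sequence[RelevanceScore],
    cfg: SplitConfig = SplitConfig(),
    analyzer=None,
) -> tuple[Corpus, Corpus]:
    """Split scored posts into (target, reference) corpora.

    target: score strictly above the upper cutoff; reference: strictly
    below the lower cutoff; both gated to ``min_words`` words.  The two
    corpora are disjoint by construction; an empty side is a hard error
    because keyness against it is undefined.
    """
    by_id = {s.post_id: s.score for s in scores}
    missing = [p.post_id for p in corpus if p.post_id not in by_id]
    if missing:
        raise ValueError(f"{len(missing)} post(s) have no score (first: {missing[0]})")
    tokens = corpus.tokens(analyzer)
    target, reference = [], []
    for p in corpus:
        if tokens[p.post_id].word_count < cfg.min_words:
            continue
        s = by_id[p.post_id]
        if s > cfg.upper_cutoff:
            target.append(p)
        elif s < cfg.lower_cutoff:
            reference.append(p)
    if not target:
        raise ValueError("target corpus is empty under these cutoffs; keyness undefined")
    if not reference:
        raise ValueError("reference corpus is empty under these cutoffs; keyness undefined")
    return (
        corpus.subset(target, f"{corpus.name}-target"),
        corpus.subset(reference, f"{corpus.name}-reference"),
    )
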