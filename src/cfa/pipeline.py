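"""End-to-end corpus construction and analysis.

Chains the four corpus-construction steps (self-report cohort,
subforum filter, condition-mention filter, relevance split) and the
keyness analysis, logging a flow-chart-style post/user count after each
stage; counts are monotonically non-increasing by construction.

The published score cutoffs only carry meaning for the dataset they
were calibrated on, so for synthetic corpora the split can instead be
calibrated from quantiles of the score distribution — the same design
as calibrating cutoffs by coding a decile sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_filter import (
    DEFAULT_PATTERNS,
    SelfReportPattern,
    filter_condition_mention,
    filter_subforum,
    filter_users,
    find_self_report_users,
)
from .corpus_io import Corpus, TermList
from .keyness_analysis import (
    FrequencyTable,
    KeynessResult,
    build_frequency_table,
    select_key_lemmas,
)
from .relevance_ranking import (
    RelevanceScore,
    SplitConfig,
    score_relevance,
    split_corpus,
)

__all__ = ["StageCount", "PipelineResult", "quantile_split_config", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StageCount:
    stage: str
    n_posts: int
    n_users: int


@dataclass
class PipelineResult:
    stages: list[StageCount]
    scores: list[RelevanceScore]
    split: SplitConfig
    target: Corpus
    reference: Corpus
    target_table: FrequencyTable
    reference_table: FrequencyTable
    keyness: list[KeynessResult] = field(default_factory=list)

    @property
    def key_lemmas(self) -> list[str]:
        return [r.lemma for r in self.keyness if r.is_key]


def quantile_split_config(
    scores: Sequence[RelevanceScore],
    upper_q: float = 0.8,
    lower_q: float = 0.5,
    min_words: int = 94,
) -> SplitConfig:
    """Derive score cutoffs from quantiles of the score distribution."""
    vals = np.array([s.score for s in scores])
    upper = float(np.quantile(vals, upper_q))
    lower = float(np.quantile(vals, lower_q))
    if not lower < upper:
        raise ValueError(
            "score quantiles collapse; cannot derive a split from this distribution"
        )
    return SplitConfig(upper_cutoff=upper, lower_cutoff=lower, min_words=min_words)


def run_pipeline(
    corpus: Corpus,
    term_list: TermList,
    condition_terms: TermList,
    allowed_subforums: Sequence[str],
    patterns: Sequence[SelfReportPattern] = DEFAULT_PATTERNS,
    split: SplitConfig | None = None,
    split_quantiles: tuple[float, float] = (0.8, 0.5),
    min_words: int = 94,
    alpha: float = 1e-4,
    min_ratio: float = 2.0,
    min_user_share: float = 0.05,
    analyzer=None,
) -> PipelineResult:
    """Run cohort detection, filtering, scoring, splitting and keyness.

    If ``split`` is None, cutoffs are calibrated from score quantiles
    (``split_quantiles``) with the given minimum post length.
    """
    stages: list[StageCount] = []

    def log_stage(stage: str, c: Corpus) -> None:
        sc = StageCount(stage, len(c), c.user_count)
        stages.append(sc)
        logger.info("%-24s %7d posts  %6d users", stage, sc.n_posts, sc.n_users)

    log_stage("all posts", corpus)

    reporters = find_self_report_users(corpus, patterns)
    cohort = filter_users(corpus, reporters, name=f"{corpus.name}-cohort")
    log_stage("self-report cohort", cohort)

    in_sub = filter_subforum(cohort, allowed_subforums, name=f"{corpus.name}-subforum")
    log_stage("condition subforums", in_sub)

    mention = filter_condition_mention(in_sub, condition_terms, analyzer,
                                       name=f"{corpus.name}-mention")
    log_stage("condition mentions", mention)

    scores = score_relevance(mention, term_list, analyzer)
    if split is None:
        split = quantile_split_config(scores, *split_quantiles, min_words=min_words)
    target, reference = split_corpus(mention, scores, split, analyzer)
    log_stage("target corpus", target)
    # the reference corpus is a side branch of the flow chart, not a
    # further narrowing of the target, so it is not a numbered stage
    logger.info("%-24s %7d posts  %6d users", "reference corpus",
                len(reference), reference.user_count)

    target_table = build_frequency_table(target, term_list, analyzer)
    reference_table = build_frequency_table(reference, term_list, analyzer)
    keyness = select_key_lemmas(target_table, reference_table, alpha=alpha,
                                min_ratio=min_ratio, min_user_share=min_user_share)
    n_key = sum(r.is_key for r in keyness)
    logger.info("key lemmas: %d of %d in union vocabulary", n_key, len(keyness))

    return PipelineResult(
        stages=stages,
        scores=scores,
        split=split,
        target=target,
        reference=reference,
        target_table=target_table,
        reference_table=reference_table,
        keyness=keyness,
    )
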