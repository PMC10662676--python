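"""Cohort detection and corpus filtering.

The first three corpus-construction steps: find users who self-report a
diagnosis in the first person ("I was diagnosed with bipolar"), keep
only posts in condition-specific subforums, and keep only posts that
mention the condition.  Filters have set-intersection semantics: they
are idempotent, order-stable and commute.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import yaml

from .corpus_io import Corpus, TermList
from .text_processing import match_terms

__all__ = [
    "SelfReportPattern",
    "SelfReportEvidence",
    "DEFAULT_PATTERNS",
    "load_patterns",
    "find_self_report_users",
    "filter_users",
    "filter_subforum",
    "filter_condition_mention",
]


@dataclass(frozen=True)
class SelfReportPattern:
    """A first-person diagnosis statement template with a ``{DX}`` slot.

    Matching is surface-level and case-insensitive with flexible
    whitespace; intervening extra tokens are not allowed (the default
    matcher is deliberately strict so third-person mentions like
    "my friend was diagnosed with bipolar" do not fire a first-person
    template).
    """

    template: str
    dx_synonyms: tuple[str, ...]

    def __post_init__(self):
        if "{DX}" not in self.template:
            raise ValueError("template must contain a {DX} slot")
        if not self.dx_synonyms:
            raise ValueError("pattern needs at least one diagnosis synonym")

    def phrases(self) -> list[str]:
        return [self.template.replace("{DX}", dx) for dx in self.dx_synonyms]

    def compile(self) -> re.Pattern:
        alts = []
        for phrase in self.phrases():
            parts = [re.escape(w) for w in phrase.split()]
            alts.append(r"\s+".join(parts))
        return re.compile(r"(?<![A-Za-z])(?:" + "|".join(alts) + r")(?![A-Za-z])",
                          re.IGNORECASE)


_BD_SYNONYMS = (
    "bipolar",
    "bipolar disorder",
    "bipolar 1",
    "bipolar 2",
    "bipolar i",
    "bipolar ii",
    "manic depression",
    "manic depressive",
)

#: Default template family around the first-person diagnosis exemplar.
DEFAULT_PATTERNS: tuple[SelfReportPattern, ...] = tuple(
    SelfReportPattern(t, _BD_SYNONYMS)
    for t in (
        "I was diagnosed with {DX}",
        "I am diagnosed with {DX}",
        "I'm diagnosed with {DX}",
        "I have been diagnosed with {DX}",
        "I've been diagnosed with {DX}",
        "I got diagnosed with {DX}",
        "my {DX} diagnosis",
        "diagnosed me with {DX}",
    )
)


def load_patterns(path) -> list[SelfReportPattern]:
    """Load patterns from YAML: a list of {template, dx_synonyms} maps."""
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ValueError(f"{path}: empty pattern file")
    return [
        SelfReportPattern(item["template"], tuple(item["dx_synonyms"]))
        for item in raw
    ]


class SelfReportEvidence(NamedTuple):
    """First matched self-report for a user, for audit."""

    post_id: str
    start: int  # character offsets into the post text
    end: int
    matched: str


def find_self_report_users(
    corpus: Corpus, patterns: Sequence[SelfReportPattern] = DEFAULT_PATTERNS
) -> dict[str, SelfReportEvidence]:
    """Users with >=1 post matching >=1 self-report pattern.

    Returns user_id -> first evidence span (post id, character offsets,
    matched text), scanning posts in corpus order.
    """
    if not patterns:
        raise ValueError("empty self-report pattern set")
    compiled = [p.compile() for p in patterns]
    found: dict[str, SelfReportEvidence] = {}
    for post in corpus:
        if post.user_id in found:
            continue
        text = post.text
        for rx in compiled:
            m = rx.search(text)
            if m:
                found[post.user_id] = SelfReportEvidence(
                    post.post_id, m.start(), m.end(), m.group(0)
                )
                break
    return found


def filter_users(corpus: Corpus, users: Iterable[str], name: str | None = None) -> Corpus:
    """Posts authored by the given users, order preserved."""
    users = set(users)
    return corpus.subset([p for p in corpus if p.user_id in users], name)


def filter_subforum(corpus: Corpus, allowed: Iterable[str], name: str | None = None) -> Corpus:
    """Posts whose subforum is in ``allowed``, order preserved."""
    allowed = set(allowed)
    if not allowed:
        raise ValueError("allowed subforum set must be non-empty")
    return corpus.subset([p for p in corpus if p.subforum in allowed], name)


def filter_condition_mention(
    corpus: Corpus, condition_terms: TermList, analyzer=None, name: str | None = None
) -> Corpus:
    """Posts with at least one term-list match for the condition."""
    if not len(condition_terms):
        raise ValueError("condition term list must be non-empty")
    tokens = corpus.tokens(analyzer)
    kept = [
        p for p in corpus if match_terms(tokens[p.post_id], condition_terms)
    ]
    return corpus.subset(kept, name)
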