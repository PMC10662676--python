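"""KWIC concordances, coding-sample workflow, and category extrapolation.

A concordance line shows one occurrence of a node lemma with up to 20
words of left and right context.  Lines are sorted by node lemma, then
left context reading outward from the node (nearest word first), then
right context; a fixed-size random sample per key lemma is exported for
human coding against a two-level coding frame, and the coded labels are
extrapolated back to corpus-level category frequencies:

    mass(category) += F(lemma) * (#coded lines labeled category / n coded)

where F is the lemma's corpus frequency.  The extrapolation is computed
in exact rational arithmetic so that, under single-label coding, the
total category mass equals the summed key-lemma frequencies exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import CodingFrame, Corpus, read_table, write_table
from .keyness_analysis import FrequencyTable

__all__ = [
    "ConcordanceLine",
    "CodedLine",
    "CategoryFrequency",
    "extract_concordances",
    "sort_concordances",
    "sample_for_coding",
    "extrapolate_category_frequencies",
    "write_concordances",
    "read_coded_lines",
]


@dataclass(frozen=True)
class ConcordanceLine:
    """One key-word-in-context view of a node-lemma occurrence.

    ``start``/``end`` are 0-based end-exclusive token indices into the
    post's token sequence; contexts hold the surfaces of up to
    ``context`` word tokens on each side, truncated at post boundaries.
    """

    post_id: str
    node_lemma: str
    start: int
    end: int
    left: tuple[str, ...]
    right: tuple[str, ...]

    @property
    def line_id(self) -> str:
        return f"{self.post_id}:{self.start}"


@dataclass(frozen=True)
class CodedLine:
    """A concordance line carrying >=1 category labels from the frame."""

    line: ConcordanceLine
    labels: frozenset[str]

    def __post_init__(self):
        if not self.labels:
            raise ValueError("coded line needs at least one label")


def extract_concordances(
    corpus: Corpus, lemma: str, context: int = 20, analyzer=None
) -> list[ConcordanceLine]:
    """One KWIC line per occurrence of ``lemma`` among word tokens.

    The number of lines equals the lemma's frequency-table count.
    """
    tokens = corpus.tokens(analyzer)
    lines: list[ConcordanceLine] = []
    for post in corpus:
        toks = tokens[post.post_id].tokens
        word_idx = [i for i, t in enumerate(toks) if t.is_word]
        positions = {i: w for w, i in enumerate(word_idx)}
        for i in word_idx:
            if toks[i].lemma != lemma:
                continue
            w = positions[i]
            left = tuple(toks[j].surface for j in word_idx[max(0, w - context): w])
            right = tuple(toks[j].surface for j in word_idx[w + 1: w + 1 + context])
            lines.append(ConcordanceLine(post.post_id, lemma, i, i + 1, left, right))
    if not lines:
        warnings.warn(f"lemma {lemma!r} does not occur in corpus {corpus.name!r}",
                      stacklevel=2)
    return lines


def _sort_key(line: ConcordanceLine):
    left_out = tuple(w.casefold() for w in reversed(line.left))
    right = tuple(w.casefold() for w in line.right)
    return (line.node_lemma, left_out, right)


def sort_concordances(lines: Sequence[ConcordanceLine]) -> list[ConcordanceLine]:
    """Stable sort by node lemma, then nearest-left word outward, then
    right context left-to-right."""
    return sorted(lines, key=_sort_key)


def sample_for_coding(
    lines: Sequence[ConcordanceLine], n: int = 30, seed: int = 0
) -> list[ConcordanceLine]:
    """Uniform sample of ``n`` lines without replacement, seeded.

    If fewer than ``n`` lines exist, all are returned with a warning.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    lines = list(lines)
    if len(lines) <= n:
        if len(lines) < n:
            warnings.warn(
                f"only {len(lines)} concordance line(s) available (< {n}); taking all",
                stacklevel=2,
            )
        return lines
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(lines), size=n, replace=False)
    return [lines[i] for i in sorted(idx)]


@dataclass
class CategoryFrequency:
    """Extrapolated instance counts per category and per domain.

    Counts are exact rationals (:class:`fractions.Fraction`); convert
    with ``float`` for display.  Domain totals are the sums over child
    categories; ``Not-frame`` forms its own pseudo-domain.
    """

    category_mass: dict[str, Fraction]
    domain_mass: dict[str, Fraction]

    @property
    def total_mass(self) -> Fraction:
        return sum(self.category_mass.values(), Fraction(0))


def extrapolate_category_frequencies(
    coded: Mapping[str, Sequence[CodedLine]],
    freq: FrequencyTable,
    frame: CodingFrame,
) -> CategoryFrequency:
    """Scale per-lemma coded-sample label shares up to corpus frequency.

    For lemma l with corpus frequency F(l) and a coded sample of n(l)
    lines, each category receives F(l) * (#lines carrying that label) /
    n(l).  Multi-label lines give every label its full proportional
    mass, so totals can exceed the summed frequencies; with single-label
    coding the total equals sum_l F(l) exactly.
    """
    category_mass: dict[str, Fraction] = {}
    for lemma, lines in coded.items():
        if lemma not in freq.freq:
            raise ValueError(f"coded lemma {lemma!r} missing from frequency table")
        lines = list(lines)
        if not lines:
            warnings.warn(f"lemma {lemma!r} has an empty coded set; excluded",
                          stacklevel=2)
            continue
        n = len(lines)
        f_lemma = freq.freq[lemma]
        label_counts: dict[str, int] = {}
        for cl in lines:
            for label in cl.labels:
                if not frame.is_valid_label(label):
                    raise ValueError(f"label {label!r} not in coding frame")
                label_counts[label] = label_counts.get(label, 0) + 1
        for label, count in label_counts.items():
            category_mass[label] = (
                category_mass.get(label, Fraction(0))
                + Fraction(f_lemma) * Fraction(count, n)
            )
    domain_mass: dict[str, Fraction] = {}
    for label, mass in category_mass.items():
        dom = frame.domain_of(label)
        domain_mass[dom] = domain_mass.get(dom, Fraction(0)) + mass
    return CategoryFrequency(category_mass, domain_mass)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def write_concordances(lines: Sequence[ConcordanceLine], path,
                       metadata: Mapping[str, str] | None = None) -> None:
    rows = [
        {
            "line_id": ln.line_id,
            "post_id": ln.post_id,
            "node_lemma": ln.node_lemma,
            "start": str(ln.start),
            "end": str(ln.end),
            "left": " ".join(ln.left),
            "right": " ".join(ln.right),
        }
        for ln in lines
    ]
    write_table(rows, path,
                fieldnames=["line_id", "post_id", "node_lemma", "start", "end",
                            "left", "right"],
                metadata=metadata)


def read_coded_lines(path, frame: CodingFrame) -> dict[str, list[CodedLine]]:
    """Read a coded-label TSV back into per-lemma CodedLine sets.

    Expected columns: the concordance columns plus ``labels`` holding
    ``|``-separated category names.
    """
    rows, _md = read_table(path)
    coded: dict[str, list[CodedLine]] = {}
    for row in rows:
        labels = frozenset(s for s in row["labels"].split("|") if s)
        line = ConcordanceLine(
            post_id=row["post_id"],
            node_lemma=row["node_lemma"],
            start=int(row["start"]),
            end=int(row["end"]),
            left=tuple(row["left"].split()) if row["left"] else (),
            right=tuple(row["right"].split()) if row["right"] else (),
        )
        for label in labels:
            if not frame.is_valid_label(label):
                raise ValueError(f"{path}: unknown label {label!r}")
        coded.setdefault(line.node_lemma, []).append(CodedLine(line, labels))
    return coded
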