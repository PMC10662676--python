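"""Collocation ranking by cubed mutual information (MI3).

For a node lemma, a collocate is any content-word lemma (noun, verb,
adjective or adverb) occurring within a symmetric window of ``window``
word positions around any node occurrence.  With O the observed
co-occurrence count, f1/f2 the node and collocate corpus frequencies,
N the corpus word-token count and W = 2*window the window width,

    E   = f1 * f2 * W / N
    MI3 = log2(O**3 / E)

The cube rewards frequent collocates, countering plain MI's bias toward
rare one-off pairings.  Windows are measured over word tokens only
(punctuation is skipped) and truncated at post boundaries; a token near
two node occurrences is counted once (union semantics), and node
occurrences are never collocates of themselves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .corpus_io import Corpus
from .text_processing import CONTENT_POS

__all__ = ["CollocationResult", "collocates"]


@dataclass(frozen=True)
class CollocationResult:
    node: str
    collocate: str
    observed: int  # O
    node_freq: int  # f1
    collocate_freq: int  # f2
    expected: float  # E
    mi3: float

    def to_row(self) -> dict[str, str]:
        return {
            "node": self.node,
            "collocate": self.collocate,
            "observed": str(self.observed),
            "node_freq": str(self.node_freq),
            "collocate_freq": str(self.collocate_freq),
            "expected": repr(self.expected),
            "mi3": repr(self.mi3),
        }


def collocates(
    corpus: Corpus,
    node: str,
    window: int = 5,
    min_freq: int = 5,
    analyzer=None,
) -> list[CollocationResult]:
    """Content-word collocates of ``node``, ranked by MI3 descending
    (ties broken by collocate lemma)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    tokens = corpus.tokens(analyzer)

    lemma_freq: dict[str, int] = {}
    lemma_pos: dict[str, str] = {}
    observed: dict[str, int] = {}
    n_tokens = 0
    f1 = 0

    for post in corpus:
        words = [t for t in tokens[post.post_id] if t.is_word]
        n = len(words)
        n_tokens += n
        node_positions = [i for i, t in enumerate(words) if t.lemma == node]
        f1 += len(node_positions)
        for t in words:
            lemma_freq[t.lemma] = lemma_freq.get(t.lemma, 0) + 1
            lemma_pos.setdefault(t.lemma, t.pos)
        if not node_positions:
            continue
        # union of window neighborhoods, node positions excluded
        in_window = set()
        for p in node_positions:
            in_window.update(range(max(0, p - window), min(n, p + window + 1)))
        in_window.difference_update(node_positions)
        for i in in_window:
            lem = words[i].lemma
            observed[lem] = observed.get(lem, 0) + 1

    if f1 == 0:
        warnings.warn(f"node lemma {node!r} absent from corpus {corpus.name!r}",
                      stacklevel=2)
        return []

    w = 2 * window
    results: list[CollocationResult] = []
    for lem, o in observed.items():
        if o < min_freq:
            continue
        if lemma_pos.get(lem) not in CONTENT_POS:
            continue
        f2 = lemma_freq[lem]
        expected = f1 * f2 * w / n_tokens
        mi3 = math.log2(o**3 / expected)
        results.append(CollocationResult(node, lem, o, f1, f2, expected, mi3))
    results.sort(key=lambda r: (-r.mi3, r.collocate))
    return results
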