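"""Tokenization, lemmatization, POS tagging, word counting and multiword
term matching.

Every statistic in the pipeline counts *lemmas* — dictionary forms of
words ("recovering", "recovered" -> "recover") — so this module is the
normalization layer the whole analysis depends on.  The analyzer is
pluggable: any object with an ``analyze(text) -> TokenSeq`` method plus
``name``/``version`` attributes can be swapped in, and the analyzer
identity is recorded in output tables so results stay reproducible.

The default :class:`RuleAnalyzer` is a deterministic rule-based
tokenizer/lemmatizer: a regex tokenizer that collapses URLs and user
mentions to non-word placeholder tokens, a small irregular-form table
plus suffix-stripping rules for lemmas, and a coarse 5-class POS tagger
(NOUN/VERB/ADJ/ADV/OTHER — only the content/function distinction matters
downstream, for the collocation content-word filter).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Token",
    "TokenSeq",
    "RuleAnalyzer",
    "get_analyzer",
    "analyze",
    "word_count",
    "match_terms",
    "CONTENT_POS",
]

POS_TAGS = ("NOUN", "VERB", "ADJ", "ADV", "OTHER")
CONTENT_POS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})


@dataclass(frozen=True)
class Token:
    """One token: surface form, lowercase lemma, coarse POS, word flag."""

    surface: str
    lemma: str
    pos: str
    is_word: bool


class TokenSeq:
    """An ordered token sequence for one text.

    ``word_count`` counts only tokens with ``is_word`` set (alphabetic or
    alphanumeric tokens; punctuation and placeholders are excluded).
    """

    __slots__ = ("tokens",)

    def __init__(self, tokens: Sequence[Token]):
        self.tokens = tuple(tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, TokenSeq) and self.tokens == other.tokens

    @property
    def word_count(self) -> int:
        return sum(1 for t in self.tokens if t.is_word)

    def word_indices(self) -> list[int]:
        """Indices of word tokens, in order."""
        return [i for i, t in enumerate(self.tokens) if t.is_word]

    def lemmas(self) -> list[str]:
        """Lemmas of word tokens only."""
        return [t.lemma for t in self.tokens if t.is_word]


# --------------------------------------------------------------------------
# Default rule-based analyzer
# --------------------------------------------------------------------------

_URL_RE = r"https?://\S+|www\.\S+"
_MENTION_RE = r"/?u/[A-Za-z0-9_-]+|@\w+"
_WORD_RE = r"[A-Za-z][A-Za-z0-9]*(?:'[A-Za-z]+)?|\d+[A-Za-z0-9]*"
_PUNCT_RE = r"[^\sA-Za-z0-9]"

_TOKEN_RE = re.compile(f"({_URL_RE})|({_MENTION_RE})|({_WORD_RE})|({_PUNCT_RE}+)")

# Intra-word hyphens are treated as separators: "self-care" tokenizes to
# two adjacent word tokens with no intervening punctuation token, so
# multiword terms can match across the hyphen.
_HYPHEN_RE = re.compile(r"(?<=[A-Za-z0-9])-(?=[A-Za-z0-9])")

# Closed function-word set: always POS OTHER, lemma via the irregular
# table or identity.  Deliberately small; anything not listed is treated
# as a content word.
FUNCTION_WORDS = frozenset(
    """
    a an the this that these those some any no every each
    i you he she it we they me him her us them my your his its our their
    mine yours hers ours theirs myself yourself himself herself itself
    ourselves themselves
    am is are was were be been being
    do does did doing done have has had having
    will would shall should can could may might must
    not n't never also just very too so
    and or but nor if then than because while although though
    of in on at by for with about against between into through during
    before after above below to from up down out off over under again
    there here when where why how what which who whom whose
    as such own same other another more most less least only both all
    yes okay ok oh
    """.split()
)

# Irregular inflections that suffix rules would mangle.  Kept modest:
# auxiliaries, high-frequency verbs, and forms that matter for the
# shipped default term lists.
IRREGULAR_LEMMAS = {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be",
    "has": "have", "had": "have", "having": "have",
    "does": "do", "did": "do", "done": "do", "doing": "do",
    "goes": "go", "went": "go", "gone": "go", "going": "go",
    "said": "say", "says": "say", "saying": "say",
    "made": "make", "making": "make",
    "got": "get", "gotten": "get", "getting": "get",
    "took": "take", "taken": "take", "taking": "take",
    "gave": "give", "given": "give", "giving": "give",
    "came": "come", "coming": "come",
    "felt": "feel", "feeling": "feel",
    "found": "find", "thought": "think", "told": "tell", "knew": "know",
    "known": "know", "saw": "see", "seen": "see",
    "diagnosed": "diagnose", "diagnoses": "diagnose", "diagnosing": "diagnose",
    "managed": "manage", "managing": "manage", "manages": "manage",
    "cured": "cure", "curing": "cure", "cures": "cure",
    "used": "use", "using": "use", "uses": "use",
    "cared": "care", "caring": "care", "cares": "care",
    "hoped": "hope", "hoping": "hope", "hopes": "hope",
    "lived": "live", "living": "live", "lives": "live",
    "struggled": "struggle", "struggling": "struggle", "struggles": "struggle",
    "accepted": "accept", "accepting": "accept", "accepts": "accept",
    "running": "run", "ran": "run",
    "better": "good", "best": "good", "worse": "bad", "worst": "bad",
    "children": "child", "men": "man", "women": "woman",
    "feet": "foot", "teeth": "tooth", "selves": "self",
}

_VOWELS = set("aeiou")


def _strip_suffix(word: str) -> str:
    """Heuristic suffix stripping for regular English inflection.

    Applied only to lowercase alphabetic words not covered by the
    irregular table.  Designed so its own outputs are fixed points
    (idempotence), which the property suite checks on synthetic corpora.
    """
    n = len(word)
    if n >= 5 and word.endswith("ies"):
        return word[:-3] + "y"
    if n >= 5 and word.endswith(("ches", "shes", "xes", "zes", "sses")):
        return word[:-2]
    if n >= 4 and word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    for suf in ("ing", "ed"):
        if n >= len(suf) + 3 and word.endswith(suf):
            stem = word[: -len(suf)]
            # undo consonant doubling: "stopping" -> "stopp" -> "stop"
            if (
                len(stem) >= 3
                and stem[-1] == stem[-2]
                and stem[-1] not in _VOWELS
                and stem[-1] not in "ls"
            ):
                stem = stem[:-1]
            return stem
    return word


def _guess_pos(surface: str, lemma: str) -> str:
    """Coarse POS from suffix shape; function words are handled earlier."""
    if lemma.endswith("ly") and len(lemma) > 3:
        return "ADV"
    if lemma.endswith(("ous", "ful", "ive", "able", "ible", "less", "ic", "al")):
        return "ADJ"
    if lemma.endswith(("ate", "ize", "ise", "ify")):
        return "VERB"
    low = surface.lower()
    if low.endswith(("ing", "ed")) and low != lemma:
        return "VERB"
    return "NOUN"


class RuleAnalyzer:
    """Deterministic rule-based analyzer (the default implementation).

    Lemmas are lowercase; URLs and user mentions become ``<URL>`` /
    ``<USER>`` placeholder tokens with ``is_word=False``.  Per-surface
    results are memoized, so repeated analysis of large corpora is cheap.
    """

    name = "rulelemma"
    version = "1"

    def __init__(self) -> None:
        self._cache: dict[str, Token] = {}

    @property
    def key(self) -> str:
        return f"{self.name}-{self.version}"

    def _classify(self, surface: str, kind: int) -> Token:
        if kind == 0:  # URL
            return Token(surface, "<url>", "OTHER", False)
        if kind == 1:  # user mention
            return Token(surface, "<user>", "OTHER", False)
        if kind == 2:  # word
            low = surface.lower()
            if low in FUNCTION_WORDS or low in {"'s", "'t", "'re", "'ve", "'ll", "'d", "'m"}:
                return Token(surface, IRREGULAR_LEMMAS.get(low, low), "OTHER", True)
            if low[0].isdigit():
                return Token(surface, low, "OTHER", True)
            lemma = IRREGULAR_LEMMAS.get(low)
            if lemma is None:
                lemma = _strip_suffix(low)
            return Token(surface, lemma, _guess_pos(surface, lemma), True)
        return Token(surface, surface, "OTHER", False)  # punctuation

    def analyze(self, text: str) -> TokenSeq:
        if not text:
            return TokenSeq(())
        text = _HYPHEN_RE.sub(" ", text)
        cache = self._cache
        tokens: list[Token] = []
        append = tokens.append
        for m in _TOKEN_RE.finditer(text):
            surface = m.group(0)
            tok = cache.get(surface)
            if tok is None:
                kind = (m.lastindex or 4) - 1
                tok = self._classify(surface, kind)
                if len(cache) < 2_000_000:
                    cache[surface] = tok
            append(tok)
        return TokenSeq(tokens)


_DEFAULT_ANALYZER: RuleAnalyzer | None = None


def get_analyzer() -> RuleAnalyzer:
    """The process-wide default analyzer (shared memo cache)."""
    global _DEFAULT_ANALYZER
    if _DEFAULT_ANALYZER is None:
        _DEFAULT_ANALYZER = RuleAnalyzer()
    return _DEFAULT_ANALYZER


def analyze(text: str, analyzer=None) -> TokenSeq:
    """Tokenize, lemmatize and POS-tag ``text`` with the given analyzer."""
    return (analyzer or get_analyzer()).analyze(text)


def word_count(text: str, analyzer=None) -> int:
    """Number of word tokens in ``text`` (the unit of the length filter)."""
    return analyze(text, analyzer).word_count


# --------------------------------------------------------------------------
# Multiword term matching
# --------------------------------------------------------------------------

def _term_index(terms: Iterable[tuple[str, ...]]):
    """Group term lemma-tuples by first lemma, longest first."""
    index: dict[str, list[tuple[str, ...]]] = {}
    for term in terms:
        index.setdefault(term[0], []).append(tuple(term))
    for lst in index.values():
        lst.sort(key=len, reverse=True)
    return index


def match_terms(tokens: TokenSeq, terms) -> list[tuple[tuple[str, ...], int, int]]:
    """Greedy left-to-right longest-match of term lemma sequences.

    Returns ``(term, start, end)`` triples with 0-based end-exclusive
    token indices.  Matched spans never overlap, and a multiword span
    must consist of consecutive *word* tokens — any non-word token
    (punctuation, URL) breaks it.
    """
    term_tuples = getattr(terms, "terms", terms)
    index = _term_index(term_tuples)
    toks = tokens.tokens
    n = len(toks)
    out: list[tuple[tuple[str, ...], int, int]] = []
    i = 0
    while i < n:
        t = toks[i]
        if not t.is_word:
            i += 1
            continue
        candidates = index.get(t.lemma)
        if candidates:
            for term in candidates:
                k = len(term)
                if i + k > n:
                    continue
                span = toks[i : i + k]
                if all(s.is_word and s.lemma == lem for s, lem in zip(span, term)):
                    out.append((term, i, i + k))
                    i += k
                    break
            else:
                i += 1
        else:
            i += 1
    return out
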