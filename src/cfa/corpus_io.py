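"""Core record types and artifact I/O.

Posts are serialized one JSON object per line (JSONL); tabular artifacts
(frequency lists, keyness tables, concordances, label files) are TSV
with an optional block of ``#``-prefixed metadata lines above the header
recording provenance such as the analyzer name/version.  Term lists are
plain text, one term per line; coding frames are YAML mappings from
domain to category list.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

from .text_processing import TokenSeq, analyze, get_analyzer

__all__ = [
    "Post",
    "Corpus",
    "TermList",
    "CodingFrame",
    "NOT_FRAME",
    "read_posts",
    "write_posts",
    "read_term_list",
    "write_term_list",
    "read_coding_frame",
    "poetic_frame",
    "write_table",
    "read_table",
]

POST_FIELDS = ("post_id", "user_id", "subforum", "created", "title", "body")

#: Label for concordance lines that do not fit any category of the frame.
NOT_FRAME = "Not-frame"


@dataclass(frozen=True)
class Post:
    """One forum contribution.

    ``created`` is an ISO-8601 UTC timestamp string; it is provenance
    only and never enters any statistic.  The analysis text is the title
    and body joined by a single newline (title first); an empty title
    contributes nothing.
    """

    post_id: str
    user_id: str
    subforum: str
    created: str
    title: str
    body: str

    @property
    def text(self) -> str:
        if self.title:
            return f"{self.title}\n{self.body}"
        return self.body


class Corpus:
    """An ordered collection of posts sampled from a forum.

    Word and user counts are pure functions of content, independent of
    record order.  Analyzed token layers are cached per analyzer so the
    many downstream statistics do not re-tokenize.
    """

    def __init__(self, posts: Sequence[Post], name: str = "corpus"):
        self.posts = list(posts)
        self.name = name
        self._token_cache: dict[str, dict[str, TokenSeq]] = {}

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Corpus)
            and self.posts == other.posts
            and self.name == other.name
        )

    @property
    def user_count(self) -> int:
        return len({p.user_id for p in self.posts})

    def users(self) -> set[str]:
        return {p.user_id for p in self.posts}

    def word_count(self, analyzer=None) -> int:
        toks = self.tokens(analyzer)
        return sum(ts.word_count for ts in toks.values())

    def tokens(self, analyzer=None) -> dict[str, TokenSeq]:
        """Mapping post_id -> analyzed TokenSeq (cached per analyzer)."""
        analyzer = analyzer or get_analyzer()
        key = getattr(analyzer, "key", repr(analyzer))
        cached = self._token_cache.get(key)
        if cached is None or len(cached) != len(self.posts):
            cached = {p.post_id: analyze(p.text, analyzer) for p in self.posts}
            self._token_cache[key] = cached
        return cached

    def subset(self, posts: Sequence[Post], name: str | None = None) -> "Corpus":
        sub = Corpus(posts, name or self.name)
        # reuse already-analyzed tokens
        ids = {p.post_id for p in posts}
        for key, cache in self._token_cache.items():
            sub._token_cache[key] = {
                pid: ts for pid, ts in cache.items() if pid in ids
            }
        return sub


# --------------------------------------------------------------------------
# Posts (JSONL)
# --------------------------------------------------------------------------

def read_posts(path, name: str | None = None) -> Corpus:
    """Read a JSONL post file into a Corpus, preserving input order.

    Unknown keys are ignored.  A missing required field or unparsable
    line is a hard error naming the field and 1-based line number.
    """
    path = Path(path)
    posts: list[Post] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            for f in POST_FIELDS:
                if f not in rec:
                    raise ValueError(f"{path}: missing required field {f!r} on line {lineno}")
            if not rec["user_id"]:
                raise ValueError(f"{path}: empty user_id on line {lineno}")
            posts.append(Post(*(str(rec[f]) for f in POST_FIELDS)))
    if not posts:
        warnings.warn(f"{path}: no posts read (empty file)", stacklevel=2)
    return Corpus(posts, name or path.stem)


def write_posts(corpus: Corpus, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in corpus:
            rec = {f: getattr(p, f) for f in POST_FIELDS}
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# --------------------------------------------------------------------------
# Term lists
# --------------------------------------------------------------------------

class TermList:
    """Ordered set of concept terms; each term is >=1 lowercase lemmas.

    Single-word and multiword terms coexist.  Duplicates after lemma
    normalization are dropped (the analogue of removing spelling and
    phraseological variants from a raw term list).
    """

    def __init__(self, terms: Sequence[tuple[str, ...]]):
        seen: set[tuple[str, ...]] = set()
        uniq: list[tuple[str, ...]] = []
        for t in terms:
            t = tuple(t)
            if not t or any(not lem for lem in t):
                raise ValueError(f"invalid term: {t!r}")
            if t not in seen:
                seen.add(t)
                uniq.append(t)
        if not uniq:
            raise ValueError("term list is empty; scoring is undefined")
        self.terms: tuple[tuple[str, ...], ...] = tuple(uniq)

    @classmethod
    def from_strings(cls, strings: Iterable[str], analyzer=None) -> "TermList":
        """Normalize raw term strings through the analyzer.

        Each line is lowercased and lemma-normalized; duplicates after
        normalization are dropped with a warning so variant spellings
        collapse onto one term.
        """
        normalized: list[tuple[str, ...]] = []
        seen: set[tuple[str, ...]] = set()
        dropped = 0
        for s in strings:
            lemmas = tuple(analyze(s, analyzer).lemmas())
            if not lemmas:
                continue
            if lemmas in seen:
                dropped += 1
                continue
            seen.add(lemmas)
            normalized.append(lemmas)
        if dropped:
            warnings.warn(
                f"dropped {dropped} duplicate term(s) after lemma normalization; "
                f"{len(normalized)} unique terms remain",
                stacklevel=2,
            )
        return cls(normalized)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __contains__(self, term) -> bool:
        return tuple(term) in set(self.terms)

    def __eq__(self, other) -> bool:
        return isinstance(other, TermList) and self.terms == other.terms

    def strings(self) -> list[str]:
        return [" ".join(t) for t in self.terms]

    @property
    def has_multiword(self) -> bool:
        return any(len(t) > 1 for t in self.terms)


def read_term_list(path, analyzer=None) -> TermList:
    """Read a plain-text term list (one term per line, ``#`` comments)."""
    path = Path(path)
    lines = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        lines.append(s)
    if not lines:
        raise ValueError(f"{path}: term list is empty; scoring is undefined")
    return TermList.from_strings(lines, analyzer)


def write_term_list(terms: TermList, path) -> None:
    Path(path).write_text(
        "".join(s + "\n" for s in terms.strings()), encoding="utf-8"
    )


# --------------------------------------------------------------------------
# Coding frame
# --------------------------------------------------------------------------

@dataclass
class CodingFrame:
    """A two-level qualitative coding frame: domains holding categories.

    Every category has exactly one parent domain.  The special label
    ``Not-frame`` is always valid and denotes lines outside the frame.
    """

    domains: list[str]
    categories: dict[str, str]  # category -> parent domain

    def __post_init__(self):
        for cat, dom in self.categories.items():
            if dom not in self.domains:
                raise ValueError(f"category {cat!r} has unknown domain {dom!r}")

    def is_valid_label(self, label: str) -> bool:
        return label == NOT_FRAME or label in self.categories

    def domain_of(self, label: str) -> str:
        if label == NOT_FRAME:
            return NOT_FRAME
        return self.categories[label]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "CodingFrame":
        domains = list(mapping)
        categories: dict[str, str] = {}
        for dom, cats in mapping.items():
            for cat in cats:
                if cat in categories:
                    raise ValueError(f"category {cat!r} appears under two domains")
                categories[cat] = dom
        return cls(domains, categories)


def read_coding_frame(path) -> CodingFrame:
    """Read a YAML mapping ``domain -> [category, ...]``."""
    with Path(path).open("r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: coding frame must be a mapping of domain -> categories")
    return CodingFrame.from_mapping(mapping)


def poetic_frame() -> CodingFrame:
    """The shipped POETIC personal-recovery frame (6 domains, 21
    categories)."""
    from importlib.resources import files

    mapping = yaml.safe_load(files("cfa").joinpath("frames/poetic.yml").read_text("utf-8"))
    return CodingFrame.from_mapping(mapping)


# --------------------------------------------------------------------------
# Generic TSV tables
# --------------------------------------------------------------------------

def write_table(records, path, fieldnames: Sequence[str] | None = None,
                metadata: Mapping[str, str] | None = None) -> None:
    """Write records (dicts sharing a schema) as TSV, header row first.

    Fields containing tabs or newlines are quoted (csv semantics).
    Optional metadata is written as ``#key\\tvalue`` lines above the
    header; readers skip them.
    """
    records = list(records)
    if fieldnames is None:
        if not records:
            raise ValueError("cannot infer header for an empty record set; pass fieldnames")
        fieldnames = list(records[0].keys())
    buf = io.StringIO()
    if metadata:
        for k, v in metadata.items():
            buf.write(f"#{k}\t{v}\n")
    writer = csv.DictWriter(buf, fieldnames=fieldnames, dialect="excel-tab",
                            lineterminator="\n")
    writer.writeheader()
    for rec in records:
        writer.writerow({k: rec.get(k, "") for k in fieldnames})
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_table(path) -> tuple[list[dict[str, str]], dict[str, str]]:
    """Read a TSV table; returns (records, metadata)."""
    metadata: dict[str, str] = {}
    body_lines: list[str] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not body_lines and line.startswith("#"):
                k, _, v = line[1:].rstrip("\n").partition("\t")
                metadata[k] = v
            else:
                body_lines.append(line)
    reader = csv.DictReader(body_lines, dialect="excel-tab")
    return [dict(row) for row in reader], metadata
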