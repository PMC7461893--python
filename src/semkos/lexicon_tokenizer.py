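"""Keyword/method lexicons and longest-phrase-first term recognition.

Two term lists are harvested from a corpus: author keywords (from keyword
sections) and method names (from the subtitles of methods-like sections).
Each surface is lowercased, ranked by frequency within its kind and given an
id ``kwd<r>`` or ``mtd<r>`` (rank 1 = most frequent). Surfaces occurring in
both lists are kept only as methods, so the two vocabularies are disjoint.

Recognition is greedy and longest-phrase-first: scanning a sentence left to
right, the longest lexicon phrase starting at each position is emitted and
its words are consumed, so a shorter phrase embedded in a longer one (e.g.
"short-term memory" inside "visual short-term memory") is not counted.
Words that are not part of any lexicon phrase are discarded.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from semkos.corpus_io import (
    ArticleRecord,
    article_text,
    extract_author_keywords,
    extract_method_subtitles,
)

__all__ = [
    "Term",
    "Lexicon",
    "TokenStream",
    "normalize_surface",
    "build_lexicon",
    "filter_lexicon",
    "recognize_terms",
    "tokenize_corpus",
    "corpus_counts",
    "write_lexicon_tsv",
    "read_lexicon_tsv",
    "write_token_streams",
    "read_token_streams",
]

# a word is an alphanumeric run, possibly with internal hyphens
# ("short-term" is one word); everything else is a boundary
_WORD_RE = re.compile(r"[0-9A-Za-zÀ-ɏ]+(?:-[0-9A-Za-zÀ-ɏ]+)*")
_SENTENCE_RE = re.compile(r"[.?!]")


def normalize_surface(raw: str) -> str:
    """Lowercase, strip, and collapse internal whitespace runs to one space."""
    return " ".join(raw.lower().split())


@dataclass(frozen=True)
class Term:
    """A lexicon entry.

    ``term_id`` encodes the kind and frequency rank (``kwd3`` = third most
    frequent keyword). ``source_count`` counts occurrences in the harvesting
    source (keyword sections, or methods subtitles); ``corpus_count`` counts
    recognized occurrences in the tokenized corpus.
    """

    surface: str
    kind: str  # "keyword" | "method"
    term_id: str
    source_count: int
    corpus_count: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("keyword", "method"):
            raise ValueError(f"kind must be 'keyword' or 'method', got {self.kind!r}")


class Lexicon:
    """A set of terms indexed by surface, partitioned by kind."""

    def __init__(self, terms: Iterable[Term]):
        self.terms: list[Term] = list(terms)
        self.by_surface: dict[str, Term] = {}
        self.by_id: dict[str, Term] = {}
        for t in self.terms:
            if t.surface in self.by_surface:
                raise ValueError(f"duplicate surface {t.surface!r} in lexicon")
            if t.term_id in self.by_id:
                raise ValueError(f"duplicate term_id {t.term_id!r} in lexicon")
            self.by_surface[t.surface] = t
            self.by_id[t.term_id] = t

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, surface: str) -> bool:
        return surface in self.by_surface

    def of_kind(self, kind: str) -> list[Term]:
        return [t for t in self.terms if t.kind == kind]

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.terms]

    def with_corpus_counts(self, counts: Mapping[str, int]) -> "Lexicon":
        """New lexicon with ``corpus_count`` filled from a surface->count map."""
        return Lexicon(
            Term(t.surface, t.kind, t.term_id, t.source_count, int(counts.get(t.surface, 0)))
            for t in self.terms
        )


@dataclass
class TokenStream:
    """Recognized term occurrences of one article, in text order.

    ``tokens`` is a list of ``(term_id, start, end)`` character spans into the
    article text; spans never overlap and strictly increase.
    """

    article_id: str
    tokens: list[tuple[str, int, int]] = field(default_factory=list)

    def term_ids(self) -> list[str]:
        return [t[0] for t in self.tokens]


def _ranked_terms(counter: Counter, kind: str, prefix: str) -> list[Term]:
    # rank by descending count, ties broken lexicographically by surface
    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        Term(surface=s, kind=kind, term_id=f"{prefix}{r}", source_count=c)
        for r, (s, c) in enumerate(ordered, start=1)
    ]


def build_lexicon(articles: Sequence[ArticleRecord]) -> Lexicon:
    """Harvest and rank keyword and method surfaces from a corpus.

    Keyword surfaces are counted over keyword sections, method surfaces over
    methods-section subtitles. A surface present in both lists is dropped
    from the keyword list (kept only as a method) so the kinds stay disjoint.
    Ids are assigned by descending source count within kind.
    """
    kwd_counts: Counter = Counter()
    mtd_counts: Counter = Counter()
    for art in articles:
        for raw in extract_author_keywords(art):
            s = normalize_surface(raw)
            if s:
                kwd_counts[s] += 1
        for raw in extract_method_subtitles(art):
            s = normalize_surface(raw)
            if s:
                mtd_counts[s] += 1
    for dup in set(kwd_counts) & set(mtd_counts):
        del kwd_counts[dup]
    terms = _ranked_terms(kwd_counts, "keyword", "kwd") + _ranked_terms(mtd_counts, "method", "mtd")
    return Lexicon(terms)


def filter_lexicon(
    lexicon: Lexicon,
    corpus_counts: Mapping[str, int] | None = None,
    *,
    keyword_min_source: int = 5,
    method_min_source: int = 2,
    min_corpus: int = 10,
) -> Lexicon:
    """Keep well-attested terms only; ids and ranks are NOT reassigned.

    Keywords are kept iff they appeared more than ``keyword_min_source`` times
    in keyword sections AND more than ``min_corpus`` times in the tokenized
    corpus; methods iff more than ``method_min_source`` times as subtitles AND
    more than ``min_corpus`` times in the corpus. Thresholds are strict
    ("more than N" means > N). Rarely attested terms get noisy embeddings,
    which would pollute the clustering tree.
    """
    lex = lexicon if corpus_counts is None else lexicon.with_corpus_counts(corpus_counts)
    kept = []
    for t in lex.terms:
        min_source = keyword_min_source if t.kind == "keyword" else method_min_source
        if t.source_count > min_source and t.corpus_count > min_corpus:
            kept.append(t)
    return Lexicon(kept)


class _PhraseIndex:
    """First-word index over lexicon phrases for greedy longest-first matching."""

    def __init__(self, lexicon: Lexicon):
        self.by_first: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        for t in lexicon.terms:
            words = tuple(t.surface.split())
            if not words:
                continue
            self.by_first.setdefault(words[0], []).append((words, t.term_id))
        for lst in self.by_first.values():
            lst.sort(key=lambda wt: -len(wt[0]))  # longest phrase first


def _iter_sentences(text: str):
    """Yield (offset, sentence) pairs split on ./?/!."""
    start = 0
    for m in _SENTENCE_RE.finditer(text):
        yield start, text[start : m.start()]
        start = m.end()
    yield start, text[start:]


def recognize_terms(text: str, lexicon: Lexicon | _PhraseIndex) -> list[tuple[str, int, int]]:
    """Greedy longest-phrase-first recognition over one text.

    Returns ``(term_id, start, end)`` character spans in text order. At each
    unconsumed word position the longest lexicon phrase starting there is
    emitted and its words consumed; matches never cross sentence boundaries
    (sentences split on ``.?!``).
    """
    index = lexicon if isinstance(lexicon, _PhraseIndex) else _PhraseIndex(lexicon)
    out: list[tuple[str, int, int]] = []
    for offset, sentence in _iter_sentences(text):
        words = [(m.group(0).lower(), m.start(), m.end()) for m in _WORD_RE.finditer(sentence)]
        i = 0
        n = len(words)
        while i < n:
            candidates = index.by_first.get(words[i][0])
            if candidates:
                for phrase, term_id in candidates:
                    k = len(phrase)
                    if i + k <= n and all(words[i + j][0] == phrase[j] for j in range(1, k)):
                        out.append((term_id, offset + words[i][1], offset + words[i + k - 1][2]))
                        i += k
                        break
                else:
                    i += 1
            else:
                i += 1
    return out


def tokenize_corpus(
    articles: Sequence[ArticleRecord], lexicon: Lexicon
) -> list[TokenStream]:
    """Tokenize title+sections of every article; non-term words are discarded."""
    index = _PhraseIndex(lexicon)
    return [
        TokenStream(article_id=a.article_id, tokens=recognize_terms(article_text(a), index))
        for a in articles
    ]


def corpus_counts(streams: Iterable[TokenStream], lexicon: Lexicon) -> dict[str, int]:
    """Surface -> recognized-occurrence count over token streams."""
    counts: Counter = Counter()
    for stream in streams:
        counts.update(stream.term_ids())
    return {lexicon.by_id[tid].surface: c for tid, c in counts.items() if tid in lexicon.by_id}


# ---------------------------------------------------------------------------
# serialization


def write_lexicon_tsv(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tkind\tsurface\tsource_count\tcorpus_count\n")
        for t in lexicon.terms:
            fh.write(f"{t.term_id}\t{t.kind}\t{t.surface}\t{t.source_count}\t{t.corpus_count}\n")


def read_lexicon_tsv(path: str | Path) -> Lexicon:
    terms = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("term_id"):
            raise ValueError(f"lexicon TSV {path} missing header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tid, kind, surface, sc, cc = line.split("\t")
            terms.append(Term(surface, kind, tid, int(sc), int(cc)))
    return Lexicon(terms)


def write_token_streams(streams: Iterable[TokenStream], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in streams:
            fh.write(
                json.dumps(
                    {"article_id": s.article_id, "tokens": [list(t) for t in s.tokens]},
                    ensure_ascii=False,
                )
            )
            fh.write("\n")


def read_token_streams(path: str | Path) -> list[TokenStream]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                TokenStream(
                    article_id=d["article_id"],
                    tokens=[(t[0], int(t[1]), int(t[2])) for t in d["tokens"]],
                )
            )
    return out
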