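"""Reading JATS/NXML article files into article records.

An :class:`ArticleRecord` keeps exactly what the downstream pipeline needs:
the title, author keywords, the section tree flattened to one level of
subtitles (method names live in the subtitles of "Materials and Methods"-like
sections), the concatenated body text, and a citation count used as the
article weight in the co-occurrence statistics.

Citation counts are not part of JATS; they are supplied through a side table
(TSV ``article_id<TAB>citations``) and default to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

__all__ = [
    "ArticleRecord",
    "SectionRecord",
    "read_jats_articles",
    "read_citation_table",
    "write_citation_table",
    "write_article_jsonl",
    "read_article_jsonl",
    "is_methods_section_title",
    "extract_method_subtitles",
    "extract_author_keywords",
    "article_text",
]


@dataclass(frozen=True)
class SectionRecord:
    """A top-level article section with its immediate subsection titles."""

    title: str
    subtitles: tuple[str, ...] = ()
    body: str = ""


@dataclass
class ArticleRecord:
    """One full-text article.

    ``citation_count`` is the article weight W used by the citation-weighted
    co-occurrence index; it is never negative.
    """

    article_id: str
    title: str = ""
    sections: list[SectionRecord] = field(default_factory=list)
    author_keywords: list[str] = field(default_factory=list)
    citation_count: int = 0

    def __post_init__(self) -> None:
        if self.citation_count < 0:
            raise ValueError(
                f"citation_count must be >= 0, got {self.citation_count} "
                f"for article {self.article_id!r}"
            )


class JATSParseError(ValueError):
    """Raised when a JATS/NXML file cannot be parsed."""


def _local(tag: str) -> str:
    """Tag name without namespace."""
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _text_of(elem) -> str:
    # element boundaries count as whitespace (titles vs following paragraphs)
    return " ".join(" ".join(elem.itertext()).split())


def _find_first(elem, name: str):
    for child in elem.iter():
        if _local(child.tag) == name:
            return child
    return None


def _children_named(elem, name: str):
    return [c for c in elem if _local(c.tag) == name]


def _parse_section(sec) -> SectionRecord:
    title_el = next((c for c in sec if _local(c.tag) == "title"), None)
    title = _text_of(title_el) if title_el is not None else ""
    subtitles = []
    body_parts = []
    for child in sec:
        name = _local(child.tag)
        if name == "sec":
            sub_title = next((c for c in child if _local(c.tag) == "title"), None)
            if sub_title is not None:
                subtitles.append(_text_of(sub_title))
            body_parts.append(_text_of(child))
        elif name != "title":
            body_parts.append(_text_of(child))
    return SectionRecord(title=title, subtitles=tuple(subtitles), body=" ".join(p for p in body_parts if p))


def _parse_article(article_el, source: str) -> ArticleRecord:
    # article id: prefer pmc/pmid <article-id>, else any article-id
    article_id = None
    ids = [e for e in article_el.iter() if _local(e.tag) == "article-id"]
    for pref in ("pmc", "pmcid", "pmid", "doi"):
        for e in ids:
            if e.get("pub-id-type") == pref:
                article_id = _text_of(e)
                break
        if article_id:
            break
    if not article_id and ids:
        article_id = _text_of(ids[0])
    if not article_id:
        raise JATSParseError(f"article without <article-id> in {source}")

    title_el = _find_first(article_el, "article-title")
    title = _text_of(title_el) if title_el is not None else ""

    keywords: list[str] = []
    for kg in (e for e in article_el.iter() if _local(e.tag) == "kwd-group"):
        for kwd in (c for c in kg.iter() if _local(c.tag) == "kwd"):
            keywords.append(_text_of(kwd))

    sections: list[SectionRecord] = []
    body_el = next((c for c in article_el if _local(c.tag) == "body"), None)
    if body_el is not None:
        for sec in _children_named(body_el, "sec"):
            sections.append(_parse_section(sec))

    return ArticleRecord(
        article_id=article_id,
        title=title,
        sections=sections,
        author_keywords=keywords,
    )


def read_jats_articles(
    path: str | Path,
    citation_table: dict[str, int] | None = None,
) -> list[ArticleRecord]:
    """Read one JATS/NXML file, or every ``*.xml``/``*.nxml`` file in a directory.

    One record is produced per ``<article>`` element, in document order.
    A missing keyword group yields empty ``author_keywords``. Citation counts
    come from ``citation_table`` (article_id -> count) and default to 0.

    Raises
    ------
    JATSParseError
        On malformed XML (the message names the file) or a duplicate
        article id across the corpus.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".xml", ".nxml"})
    else:
        files = [path]

    records: list[ArticleRecord] = []
    seen: set[str] = set()
    for f in files:
        try:
            tree = etree.parse(str(f))
        except (etree.XMLSyntaxError, OSError) as exc:
            raise JATSParseError(f"cannot parse {f}: {exc}") from exc
        root = tree.getroot()
        if _local(root.tag) == "article":
            article_els = [root]
        else:
            article_els = [e for e in root.iter() if _local(e.tag) == "article"]
        for el in article_els:
            rec = _parse_article(el, str(f))
            if rec.article_id in seen:
                raise JATSParseError(f"duplicate article_id {rec.article_id!r} in {f}")
            seen.add(rec.article_id)
            records.append(rec)

    if citation_table:
        for rec in records:
            rec.citation_count = int(citation_table.get(rec.article_id, 0))
    return records


def is_methods_section_title(title: str) -> bool:
    """True iff the lowercased title contains "method" or "procedure".

    Matches "Methods", "Materials and Methods", "Experimental procedures",
    "Methodology", ...
    """
    low = title.lower()
    return "method" in low or "procedure" in low


def extract_method_subtitles(article: ArticleRecord) -> list[str]:
    """Subtitles of every methods-like section, in document order.

    The immediate subsection titles of a matched section name the
    experimental methods used by the article.
    """
    out: list[str] = []
    for sec in article.sections:
        if is_methods_section_title(sec.title):
            out.extend(sec.subtitles)
    return out


def extract_author_keywords(article: ArticleRecord) -> list[str]:
    """Raw author-keyword strings in document order (duplicates kept)."""
    return list(article.author_keywords)


def article_text(article: ArticleRecord) -> str:
    """Title plus all section text, concatenated with sentence breaks.

    This is the text fed to term recognition; the period separators keep
    phrase matches from crossing title/section boundaries.
    """
    parts = [article.title]
    for sec in article.sections:
        parts.append(sec.title)
        parts.append(sec.body)
    return " . ".join(p for p in parts if p)


# ---------------------------------------------------------------------------
# serialization


def read_citation_table(path: str | Path) -> dict[str, int]:
    """Read a ``article_id<TAB>citations`` TSV (with header) into a dict."""
    table: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("article_id"):
            raise ValueError(f"citation table {path} missing 'article_id' header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            aid, cites = line.split("\t")
            table[aid] = int(cites)
    return table


def write_citation_table(table: dict[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("article_id\tcitations\n")
        for aid, cites in table.items():
            fh.write(f"{aid}\t{cites}\n")


def write_article_jsonl(records: Iterable[ArticleRecord], path: str | Path) -> None:
    """Serialize records as JSON-lines, one article per line, UTF-8."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(asdict(rec), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def _record_from_dict(d: dict) -> ArticleRecord:
    sections = [
        SectionRecord(title=s["title"], subtitles=tuple(s["subtitles"]), body=s["body"])
        for s in d["sections"]
    ]
    return ArticleRecord(
        article_id=d["article_id"],
        title=d["title"],
        sections=sections,
        author_keywords=list(d["author_keywords"]),
        citation_count=int(d["citation_count"]),
    )


def read_article_jsonl(path: str | Path) -> list[ArticleRecord]:
    with open(path, encoding="utf-8") as fh:
        return [_record_from_dict(json.loads(line)) for line in fh if line.strip()]
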