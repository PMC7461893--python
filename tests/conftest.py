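import pytest

from semkos.corpus_io import ArticleRecord, SectionRecord
from semkos.lexicon_tokenizer import Lexicon, Term, build_lexicon, tokenize_corpus
from semkos.synthetic_corpus import PlantedSpec, generate_corpus

JATS_ONE = """<?xml version="1.0" encoding="UTF-8"?>
<article article-type="research-article">
 <front><article-meta>
  <article-id pub-id-type="pmc">PMC0001</article-id>
  <title-group><article-title>Hippocampus and memory</article-title></title-group>
  <kwd-group><kwd>Hippocampus</kwd><kwd>Memory</kwd></kwd-group>
 </article-meta></front>
 <body>
  <sec><title>Materials and Methods</title>
   <sec><title>Statistical analysis</title><p>we used anova.</p></sec>
   <sec><title>Immunohistochemistry</title><p>we stained tissue.</p></sec>
  </sec>
  <sec><title>Results</title><p>hippocampus is required for memory.</p></sec>
 </body>
</article>
"""


def make_lexicon(keywords=(), methods=()):
    """Hand-built lexicon with ranks following the given order."""
    terms = [
        Term(surface=s, kind="keyword", term_id=f"kwd{i}", source_count=100 - i)
        for i, s in enumerate(keywords, start=1)
    ]
    terms += [
        Term(surface=s, kind="method", term_id=f"mtd{i}", source_count=100 - i)
        for i, s in enumerate(methods, start=1)
    ]
    return Lexicon(terms)


def make_article(article_id, body="", keywords=(), methods_subtitles=(), citations=0, title=""):
    sections = []
    if methods_subtitles:
        sections.append(
            SectionRecord(
                title="Materials and Methods",
                subtitles=tuple(methods_subtitles),
                body=" ".join(f"{s} applied." for s in methods_subtitles),
            )
        )
    if body:
        sections.append(SectionRecord(title="Results", subtitles=(), body=body))
    return ArticleRecord(
        article_id=article_id,
        title=title,
        sections=sections,
        author_keywords=list(keywords),
        citation_count=citations,
    )


@pytest.fixture
def two_kos():
    """Tiny hand-built keyword and method KOS (one annotation each)."""
    from semkos.tree_kos import KOS, MergeTree, annotate_cluster

    kwd_tree = MergeTree(3, ["kwd1", "kwd2", "kwd9"], [(1, 2, 0.5), (4, 3, 1.0)])
    kwd = KOS(kwd_tree)
    annotate_cluster(kwd, {4}, "KA")  # covers kwd1, kwd2; kwd9 uncovered
    mtd_tree = MergeTree(2, ["mtd1", "mtd2"], [(1, 2, 0.7)])
    mtd = KOS(mtd_tree)
    annotate_cluster(mtd, {1}, "MB")  # covers mtd1 only
    return kwd, mtd


SMALL_SPEC = PlantedSpec(
    n_keyword_groups=4,
    terms_per_group=5,
    n_method_groups=3,
    n_articles=250,
    seed=7,
)


@pytest.fixture(scope="session")
def small_corpus():
    """A small planted corpus shared across tests (read-only)."""
    return generate_corpus(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_tokenized(small_corpus):
    records, truth = small_corpus
    lexicon = build_lexicon(records)
    streams = tokenize_corpus(records, lexicon)
    return records, truth, lexicon, streams
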