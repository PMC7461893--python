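"""Synthetic JATS-like corpora with planted structure, for pipeline testing.

The generator emulates the corpus statistics the pipeline relies on, with a
known ground truth to score recovery against:

* planted keyword groups: each article has a topic, its author keywords and
  body mentions are drawn from the topic's keyword group, and same-group
  terms share a pool of group-specific context words (``group_separation``
  is the probability a context word is group-specific rather than shared);
* a methods section whose subtitles are drawn from planted method groups;
* optional keyword-group x method-group affinity: one pair's sampling rate
  is boosted by a multiplier, planting a dominant cell in the
  citation-weighted co-occurrence matrix;
* nested multiword phrases (a longer keyword phrase containing a shorter
  lexicon phrase) to exercise longest-phrase-first recognition;
* heavy-tailed citation counts drawn by inverse CDF from a truncated
  discrete power law on 0..10,000.

Everything is deterministic per seed. What the generator does *not* emulate:
real syntax or grammar, polysemy, section layout variation beyond the
methods-title synonyms, or citation-network dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from semkos.corpus_io import ArticleRecord, SectionRecord, write_citation_table
from semkos.lexicon_tokenizer import build_lexicon, corpus_counts, filter_lexicon, tokenize_corpus
from semkos.cooccurrence import (
    ArticleClusterCounts,
    aggregate_correlation,
    article_correlation,
    rank_top_combinations,
)

__all__ = [
    "PlantedSpec",
    "GroundTruth",
    "generate_corpus",
    "write_corpus",
    "score_recovery",
    "affinity_pair_rank",
    "keyword_recovery_ari",
    "sample_discrete_power_law",
    "sample_power_law_citations",
]

_METHODS_TITLES = ("Materials and Methods", "Methods", "Experimental procedures")
_CITATION_SUPPORT_MAX = 10_000


@dataclass(frozen=True)
class PlantedSpec:
    """Generator parameters; the defaults define the reference study corpus."""

    n_keyword_groups: int = 10
    terms_per_group: int = 8
    n_method_groups: int = 5
    nested_phrase_pairs: tuple[tuple[str, str], ...] = (
        ("visual short-term memory", "short-term memory"),
    )
    context_pool_size: int = 30
    group_separation: float = 0.9
    affinity_block: tuple[int, int, float] | None = None  # (kwd grp, mtd grp, mult)
    n_articles: int = 2000
    citation_tail_exponent: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_keyword_groups, self.terms_per_group, self.n_method_groups, self.n_articles) < 1:
            raise ValueError("all counts must be >= 1")
        if not (0.0 <= self.group_separation <= 1.0):
            raise ValueError("group_separation must be in [0, 1]")
        if self.affinity_block is not None:
            gk, gm, mult = self.affinity_block
            if not (0 <= gk < self.n_keyword_groups and 0 <= gm < self.n_method_groups):
                raise ValueError("affinity_block group indices out of range")
            if mult < 1:
                raise ValueError("affinity multiplier must be >= 1")
        for longer, shorter in self.nested_phrase_pairs:
            lw, sw = longer.split(), shorter.split()
            ok = any(lw[i : i + len(sw)] == sw for i in range(len(lw) - len(sw) + 1))
            if not ok or longer == shorter:
                raise ValueError(
                    f"nested pair {(longer, shorter)!r}: the shorter phrase must be a "
                    "proper contiguous sub-phrase of the longer one"
                )


@dataclass
class GroundTruth:
    """Planted labels: term surface -> group, article -> topic, affinity pair."""

    keyword_groups: dict[str, int]  # keyword surface -> group index
    method_groups: dict[str, int]  # method surface -> group index
    article_topics: dict[str, int]  # article_id -> keyword group index
    affinity_pair: tuple[str, str] | None  # (kwd group name, mtd group name)

    @staticmethod
    def kwd_group_name(g: int) -> str:
        return f"kwd-group-{g + 1}"

    @staticmethod
    def mtd_group_name(g: int) -> str:
        return f"mtd-group-{g + 1}"


def sample_discrete_power_law(
    n: int, exponent: float, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draws from p(x) ~ x^-exponent on the integers lo..hi."""
    support = np.arange(lo, hi + 1)
    cdf = np.cumsum(support.astype(float) ** (-exponent))
    cdf /= cdf[-1]
    return support[np.searchsorted(cdf, rng.random(n))]


def sample_power_law_citations(
    n: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed citation counts: Zipf p(c) ~ c^-exponent on c = 1..10,000."""
    return sample_discrete_power_law(n, exponent, 1, _CITATION_SUPPORT_MAX, rng)


def _vocabulary(spec: PlantedSpec):
    kwd_groups: list[list[str]] = []
    for g in range(spec.n_keyword_groups):
        terms = []
        for t in range(spec.terms_per_group):
            base = f"kw{g + 1}x{t + 1}"
            terms.append(f"{base} assay" if t % 4 == 3 else base)
        kwd_groups.append(terms)
    # nested phrases live in group 0 so they have coherent context
    for longer, shorter in spec.nested_phrase_pairs:
        for phrase in (shorter, longer):
            if phrase not in kwd_groups[0]:
                kwd_groups[0].append(phrase)
    mtd_groups = [
        [
            f"mt{g + 1}x{t + 1} analysis" if t % 3 == 2 else f"mt{g + 1}x{t + 1}"
            for t in range(spec.terms_per_group)
        ]
        for g in range(spec.n_method_groups)
    ]
    ctx_groups = [
        [f"ctx{g + 1}w{i + 1}" for i in range(spec.context_pool_size)]
        for g in range(spec.n_keyword_groups)
    ]
    shared_ctx = [f"shr{i + 1}" for i in range(spec.context_pool_size)]
    return kwd_groups, mtd_groups, ctx_groups, shared_ctx


def _method_group_weights(spec: PlantedSpec, topic: int) -> np.ndarray:
    w = np.ones(spec.n_method_groups)
    if spec.affinity_block is not None:
        gk, gm, mult = spec.affinity_block
        if topic == gk:
            w[gm] = mult
    return w / w.sum()


def generate_corpus(spec: PlantedSpec) -> tuple[list[ArticleRecord], GroundTruth]:
    """Generate article records plus their planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    kwd_groups, mtd_groups, ctx_groups, shared_ctx = _vocabulary(spec)
    citations = sample_power_law_citations(spec.n_articles, spec.citation_tail_exponent, rng)

    records: list[ArticleRecord] = []
    topics: dict[str, int] = {}
    for a in range(spec.n_articles):
        aid = f"SYN{a + 1:06d}"
        topic = int(rng.integers(spec.n_keyword_groups))
        topics[aid] = topic
        group_terms = kwd_groups[topic]
        mtd_w = _method_group_weights(spec, topic)

        n_kwds = int(rng.integers(3, 6))
        kwd_idx = rng.choice(len(group_terms), size=min(n_kwds, len(group_terms)), replace=False)
        keywords = [group_terms[i].capitalize() if rng.random() < 0.3 else group_terms[i] for i in kwd_idx]

        n_subs = int(rng.integers(2, 5))
        sub_groups = rng.choice(spec.n_method_groups, size=n_subs, p=mtd_w)
        subtitles, sub_paras = [], []
        for mg in sub_groups:
            m = mtd_groups[mg][int(rng.integers(len(mtd_groups[mg])))]
            subtitles.append(m.capitalize())
            ctx = ctx_groups[topic] if rng.random() < spec.group_separation else shared_ctx
            filler = [ctx[int(rng.integers(len(ctx)))] for _ in range(3)]
            sub_paras.append(f"we applied {m} with {' '.join(filler)}.")
        methods_body = " ".join(f"{s} {p}" for s, p in zip(subtitles, sub_paras))

        n_sent = int(rng.integers(5, 9))
        sentences = []
        for _ in range(n_sent):
            words: list[str] = []
            for _ in range(int(rng.integers(2, 4))):  # topic keyword mentions
                words.append(group_terms[int(rng.integers(len(group_terms)))])
            mg = int(rng.choice(spec.n_method_groups, p=mtd_w))
            words.append(mtd_groups[mg][int(rng.integers(len(mtd_groups[mg])))])
            target_len = int(rng.integers(8, 21))
            while sum(len(w.split()) for w in words) < target_len:
                ctx = ctx_groups[topic] if rng.random() < spec.group_separation else shared_ctx
                words.append(ctx[int(rng.integers(len(ctx)))])
            order = rng.permutation(len(words))
            sentences.append(" ".join(words[i] for i in order) + ".")
        results_body = " ".join(sentences)

        title_terms = group_terms[int(rng.integers(len(group_terms)))]
        records.append(
            ArticleRecord(
                article_id=aid,
                title=f"a study of {title_terms}",
                sections=[
                    SectionRecord(
                        title=str(_METHODS_TITLES[int(rng.integers(len(_METHODS_TITLES)))]),
                        subtitles=tuple(subtitles),
                        body=methods_body,
                    ),
                    SectionRecord(title="Results", subtitles=(), body=results_body),
                ],
                author_keywords=keywords,
                citation_count=int(citations[a]),
            )
        )

    truth = GroundTruth(
        keyword_groups={t: g for g, terms in enumerate(kwd_groups) for t in terms},
        method_groups={t: g for g, terms in enumerate(mtd_groups) for t in terms},
        article_topics=topics,
        affinity_pair=(
            (
                GroundTruth.kwd_group_name(spec.affinity_block[0]),
                GroundTruth.mtd_group_name(spec.affinity_block[1]),
            )
            if spec.affinity_block is not None
            else None
        ),
    )
    return records, truth


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _article_xml(rec: ArticleRecord) -> str:
    lines = [
        '<article xmlns:xlink="http://www.w3.org/1999/xlink" article-type="research-article">',
        "  <front><article-meta>",
        f'    <article-id pub-id-type="pmc">{_escape(rec.article_id)}</article-id>',
        f"    <title-group><article-title>{_escape(rec.title)}</article-title></title-group>",
        "    <kwd-group>",
    ]
    lines += [f"      <kwd>{_escape(k)}</kwd>" for k in rec.author_keywords]
    lines += ["    </kwd-group>", "  </article-meta></front>", "  <body>"]
    for sec in rec.sections:
        lines.append(f"    <sec><title>{_escape(sec.title)}</title>")
        if sec.subtitles:
            # split the stored body back into one paragraph per subtitle
            parts = sec.body
            for sub in sec.subtitles:
                parts = parts.replace(f"{sub} ", "\x00", 1)
            paras = [p for p in parts.split("\x00") if p]
            for sub, para in zip(sec.subtitles, paras):
                lines.append(
                    f"      <sec><title>{_escape(sub)}</title><p>{_escape(para.strip())}</p></sec>"
                )
        elif sec.body:
            lines.append(f"      <p>{_escape(sec.body)}</p>")
        lines.append("    </sec>")
    lines += ["  </body>", "</article>"]
    return "\n".join(lines) + "\n"


def write_corpus(
    records: Sequence[ArticleRecord],
    truth: GroundTruth,
    out_dir: str | Path,
    articles_per_file: int = 500,
) -> None:
    """Write NXML article files, the ground-truth JSON and the citation TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = '<?xml version="1.0" encoding="UTF-8"?>\n<pmc-articleset>\n'
    for start in range(0, len(records), articles_per_file):
        chunk = records[start : start + articles_per_file]
        body = "".join(_article_xml(r) for r in chunk)
        path = out / f"articles_{start // articles_per_file + 1:03d}.nxml"
        path.write_text(header + body + "</pmc-articleset>\n", encoding="utf-8")
    write_citation_table({r.article_id: r.citation_count for r in records}, out / "citations.tsv")
    (out / "ground_truth.json").write_text(
        json.dumps(asdict(truth), sort_keys=True, indent=1), encoding="utf-8"
    )


def score_recovery(
    predicted: Mapping[str, int] | Sequence[set[str]],
    truth_labels: Mapping[str, int],
) -> dict[str, float]:
    """Adjusted Rand index between a predicted partition and planted labels.

    ``predicted`` is either item -> cluster label or a list of item sets.
    Both partitions must cover the same universe of items.
    """
    if not isinstance(predicted, Mapping):
        predicted = {item: i for i, group in enumerate(predicted) for item in group}
    if set(predicted) != set(truth_labels):
        missing = set(truth_labels) ^ set(predicted)
        raise ValueError(f"partitions cover different universes (symmetric diff {len(missing)})")
    items = sorted(predicted)
    ari = adjusted_rand_score(
        [truth_labels[i] for i in items], [predicted[i] for i in items]
    )
    return {"ari": float(ari)}


def keyword_recovery_ari(
    spec: PlantedSpec,
    dimension: int = 50,
    epochs: int = 10,
    backend: str = "sgns",
) -> float:
    """End-to-end planted-group recovery score for one generated corpus.

    Runs the whole pipeline - generate, build lexicon, tokenize, embed,
    normalize, cluster with average linkage, cut the keyword tree at the
    planted group count - and returns the adjusted Rand index of the cut
    against the planted keyword groups (restricted to terms that survived
    the embedding's min_count, which all do under the default conditions).
    """
    from semkos.embedding import EmbeddingConfig, normalize_vectors, train_embeddings
    from semkos.tree_kos import agglomerate_average_linkage, cut_tree, pairwise_distances

    records, truth = generate_corpus(spec)
    lexicon = build_lexicon(records)
    streams = tokenize_corpus(records, lexicon)
    config = EmbeddingConfig(
        dimension=dimension, epochs=epochs, random_seed=spec.seed, backend=backend
    )
    table = normalize_vectors(train_embeddings(streams, config))
    kwd_ids = sorted(
        (t for t in table.term_vectors if t.startswith("kwd")), key=lambda t: int(t[3:])
    )
    tree = agglomerate_average_linkage(pairwise_distances(table, kwd_ids), kwd_ids)
    surface = {t.term_id: t.surface for t in lexicon.terms}
    predicted = [
        {surface[tid] for tid in cluster} for cluster in cut_tree(tree, spec.n_keyword_groups)
    ]
    universe = set().union(*predicted)
    planted = {s: g for s, g in truth.keyword_groups.items() if s in universe}
    return score_recovery(predicted, planted)["ari"]


def affinity_pair_rank(
    records: Sequence[ArticleRecord], truth: GroundTruth
) -> int:
    """Rank (1 = first) of the planted pair in the aggregated correlation matrix.

    Uses the planted groups themselves as clusters, so this scores the
    co-occurrence machinery against the generator's block model independent
    of embedding quality.
    """
    if truth.affinity_pair is None:
        raise ValueError("corpus was generated without an affinity block")
    lexicon = build_lexicon(records)
    streams = tokenize_corpus(records, lexicon)
    lexicon = lexicon.with_corpus_counts(corpus_counts(streams, lexicon))
    kwd_of = {t.term_id: truth.keyword_groups.get(t.surface) for t in lexicon.terms}
    mtd_of = {t.term_id: truth.method_groups.get(t.surface) for t in lexicon.terms}
    cites = {r.article_id: r.citation_count for r in records}
    rows = [GroundTruth.kwd_group_name(g) for g in range(max(truth.keyword_groups.values()) + 1)]
    cols = [GroundTruth.mtd_group_name(g) for g in range(max(truth.method_groups.values()) + 1)]
    contributions = []
    for s in streams:
        K: dict[str, int] = {}
        M: dict[str, int] = {}
        for tid in s.term_ids():
            g = kwd_of.get(tid)
            if g is not None:
                name = GroundTruth.kwd_group_name(g)
                K[name] = K.get(name, 0) + 1
            g = mtd_of.get(tid)
            if g is not None:
                name = GroundTruth.mtd_group_name(g)
                M[name] = M.get(name, 0) + 1
        counts = ArticleClusterCounts(s.article_id, cites[s.article_id], K, M)
        contributions.append(article_correlation(counts, rows, cols))
    matrix = aggregate_correlation(contributions)
    ranking = rank_top_combinations(matrix, len(rows) * len(cols))
    for rank, (kc, mc, _) in enumerate(ranking, start=1):
        if (kc, mc) == truth.affinity_pair:
            return rank
    raise AssertionError("planted pair missing from ranking")
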