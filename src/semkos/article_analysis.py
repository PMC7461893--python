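"""Retrieval and profiling of article groups through the KOS.

A cluster of the KOS doubles as a retrieval query: every article whose
token stream contains at least one member term belongs to the group. Group
structure is explored by clustering document vectors with affinity
propagation, applied in rounds (round r > 1 clusters the exemplar vectors
of round r - 1) to climb from hundreds of fine clusters to a handful of
coarse ones. Groups are profiled by their coverage vector - per term
cluster, the fraction of group articles containing at least one member
term - and subgroups by the coverage difference against a reference group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import affinity_propagation as _sk_affinity_propagation
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import euclidean_distances

from semkos.lexicon_tokenizer import TokenStream
from semkos.tree_kos import KOS, ClusterAnnotation

__all__ = [
    "ArticleGroup",
    "APResult",
    "ClusterRounds",
    "retrieve_articles",
    "affinity_propagation",
    "multiround_cluster",
    "coverage_vector",
    "coverage_difference",
    "profile_article_group",
    "write_profile_tsv",
]


@dataclass(frozen=True)
class ArticleGroup:
    """A named, non-empty set of article ids."""

    group_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"article group {self.group_id!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def retrieve_articles(
    annotation: ClusterAnnotation,
    kos: KOS,
    streams: Sequence[TokenStream],
    group_id: str | None = None,
) -> ArticleGroup:
    """Articles containing at least one member term of a cluster."""
    member_terms = set(kos.members(annotation))
    if not member_terms:
        raise ValueError(f"cluster {annotation.name!r} has no member terms")
    hits = {
        s.article_id for s in streams if member_terms.intersection(s.term_ids())
    }
    if not hits:
        raise ValueError(f"no article contains a term of cluster {annotation.name!r}")
    return ArticleGroup(group_id=group_id or annotation.name, members=frozenset(hits))


@dataclass
class APResult:
    """One affinity-propagation round: unit -> exemplar assignment."""

    labels: dict[str, int]  # unit id -> cluster index
    exemplars: list[str]  # cluster index -> exemplar unit id
    converged: bool

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def cluster_members(self, index: int) -> list[str]:
        return sorted(u for u, c in self.labels.items() if c == index)


# affinity-propagation settings pinned for reproducibility across
# environments: similarity = negative squared Euclidean distance,
# preference = median similarity, damping 0.5, 200/15 iterations
_AP_KWARGS = dict(damping=0.5, max_iter=200, convergence_iter=15, random_state=0)


def affinity_propagation(
    vectors: Mapping[str, np.ndarray],
    damping: float = 0.5,
    max_iter: int = 200,
    convergence_iter: int = 15,
) -> APResult:
    """Exemplar clustering of unit vectors by affinity propagation.

    Needs no preset cluster count. On non-convergence a warning is issued
    and the last-iteration labels are returned with ``converged=False``
    (every point its own exemplar in the degenerate sklearn fallback).
    """
    ids = sorted(vectors)
    if len(ids) < 2:
        raise ValueError("affinity propagation needs at least 2 units")
    X = np.stack([np.asarray(vectors[i], float) for i in ids])
    S = -euclidean_distances(X, squared=True)
    kwargs = dict(_AP_KWARGS, damping=damping, max_iter=max_iter, convergence_iter=convergence_iter)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        centers, labels, n_iter = _sk_affinity_propagation(
            S, preference=np.median(S), return_n_iter=True, **kwargs
        )
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                "affinity propagation did not converge; returning last-iteration labels",
                stacklevel=2,
            )
    if len(centers) == 0 or (labels < 0).any():
        # degenerate non-convergence: fall back to singleton clusters
        converged = False
        centers = np.arange(len(ids))
        labels = np.arange(len(ids))
    return APResult(
        labels={ids[i]: int(labels[i]) for i in range(len(ids))},
        exemplars=[ids[c] for c in centers],
        converged=converged,
    )


@dataclass
class ClusterRounds:
    """Multi-round affinity-propagation result.

    ``rounds[0]`` partitions the articles; round r > 0 partitions the
    exemplar vectors of round r - 1. ``top_assignment`` composes the rounds
    into article -> top-level cluster index.
    """

    rounds: list[APResult] = field(default_factory=list)
    stopped_early: bool = False

    @property
    def cluster_counts(self) -> list[int]:
        return [r.n_clusters for r in self.rounds]

    @property
    def top_assignment(self) -> dict[str, int]:
        assign = dict(self.rounds[0].labels)
        for r in range(1, len(self.rounds)):
            # article -> previous exemplar -> this round's cluster
            prev_exemplars = self.rounds[r - 1].exemplars
            cur = self.rounds[r].labels
            assign = {a: cur[prev_exemplars[c]] for a, c in assign.items()}
        return assign


def multiround_cluster(
    doc_vectors: Mapping[str, np.ndarray], rounds: int = 3
) -> ClusterRounds:
    """Cluster article vectors, then repeatedly cluster the exemplars.

    Cluster counts are weakly decreasing across rounds; if a round yields a
    single cluster (or a single exemplar remains) before the requested
    rounds are exhausted, clustering stops early with a note.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    result = ClusterRounds()
    current: Mapping[str, np.ndarray] = dict(doc_vectors)
    for _ in range(rounds):
        if len(current) < 2:
            result.stopped_early = True
            break
        res = affinity_propagation(current)
        result.rounds.append(res)
        if res.n_clusters <= 1:
            result.stopped_early = True
            break
        current = {e: current[e] for e in res.exemplars}
    if not result.rounds:
        raise ValueError("fewer than 2 document vectors; nothing to cluster")
    return result


def coverage_vector(
    group: ArticleGroup, streams: Sequence[TokenStream], kos: KOS
) -> dict[str, float]:
    """Per level-2 cluster, the fraction of group articles covering it.

    An article covers a term cluster if it contains at least one member
    term of that cluster.
    """
    level2 = kos.level2()
    stream_terms = {
        s.article_id: set(s.term_ids()) for s in streams if s.article_id in group.members
    }
    n = len(group)
    out: dict[str, float] = {}
    for ann in level2:
        member_terms = set(kos.members(ann))
        covered = sum(1 for terms in stream_terms.values() if terms & member_terms)
        out[ann.name] = covered / n
    return out


def coverage_difference(
    subgroup: ArticleGroup,
    reference: ArticleGroup,
    streams: Sequence[TokenStream],
    kos: KOS,
) -> dict[str, float]:
    """Subgroup coverage minus reference coverage, per level-2 cluster.

    Large positive entries mark what the subgroup over-represents relative
    to the reference collection.
    """
    sub = coverage_vector(subgroup, streams, kos)
    ref = coverage_vector(reference, streams, kos)
    return {name: sub[name] - ref.get(name, 0.0) for name in sub}


def _topk(values: dict[str, float], k: int, exclude: set[str]) -> list[tuple[str, float]]:
    items = [(name, v) for name, v in values.items() if name not in exclude]
    items.sort(key=lambda nv: (-nv[1], nv[0]))
    return items[:k]


def profile_article_group(
    group: ArticleGroup,
    streams: Sequence[TokenStream],
    kwd_kos: KOS,
    mtd_kos: KOS,
    citations: Mapping[str, int],
    k: int = 10,
    reference: ArticleGroup | None = None,
    exclude_keyword_clusters: set[str] | None = None,
) -> dict:
    """Top-k keyword and method clusters of a group, plus most-cited members.

    Relevance is coverage for a whole collection, and coverage difference
    against ``reference`` for a subgroup. The retrieval cluster itself is
    normally excluded from the keyword ranking (pass it via
    ``exclude_keyword_clusters``). Also lists the k most-cited member
    articles.
    """
    if reference is None:
        kwd_scores = coverage_vector(group, streams, kwd_kos)
        mtd_scores = coverage_vector(group, streams, mtd_kos)
    else:
        kwd_scores = coverage_difference(group, reference, streams, kwd_kos)
        mtd_scores = coverage_difference(group, reference, streams, mtd_kos)
    exclude = exclude_keyword_clusters or set()
    top_cited = sorted(
        group.members, key=lambda a: (-int(citations.get(a, 0)), a)
    )[:k]
    return {
        "group_id": group.group_id,
        "n_articles": len(group),
        "top_keyword_clusters": _topk(kwd_scores, k, exclude),
        "top_method_clusters": _topk(mtd_scores, k, set()),
        "top_cited_articles": [(a, int(citations.get(a, 0))) for a in top_cited],
    }


def write_profile_tsv(profile: dict, path) -> None:
    """Profile report mirroring a ranked-coverage table layout."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ID\tCluster name\tCoverage\n")
        rank = 1
        for section in ("top_keyword_clusters", "top_method_clusters"):
            for name, value in profile[section]:
                fh.write(f"{rank}\t{name}\t{100.0 * value:.2f}\n")
                rank += 1
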