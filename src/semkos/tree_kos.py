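"""Average-linkage merge trees over term vectors and their curation into a KOS.

The binary merge tree follows a fixed labeling convention: with n leaves,
labels 1..n are the leaves (in input order) and the k-th merge creates node
n+k, so the root is 2n-1. Merge height is the average pairwise distance
between the two merged clusters; average linkage is reducible, so heights
are non-decreasing along the merge order.

Curation turns branches of the tree into a knowledge organization system
(KOS): a reviewer samples a few representative leaves per branch
(:func:`sample_branch_for_review`), names branches as level-2 clusters
(:func:`annotate_cluster`; several sibling branches may share one name when
a paraphyletic group reads as one concept), and the level-2 clusters are
re-clustered by their mean member vectors into coarser level-3 groups
(:func:`regroup_level3`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from semkos.embedding import VectorTable

__all__ = [
    "MergeTree",
    "ClusterAnnotation",
    "KOS",
    "pairwise_distances",
    "agglomerate_average_linkage",
    "branch_terms",
    "cut_tree",
    "sample_branch_for_review",
    "annotate_cluster",
    "annotate_from_cut",
    "cluster_representation",
    "regroup_level3",
    "layout_landscape",
    "export_tree",
    "tree_from_json",
    "write_kos_tsv",
    "read_kos_tsv",
]


@dataclass
class MergeTree:
    """Binary agglomeration tree with 1-based node labels.

    ``leaf_terms[i-1]`` is the term at leaf label ``i``; ``merges[k-1]``
    is ``(child_a, child_b, height)`` and creates node ``n_leaves + k``.
    """

    n_leaves: int
    leaf_terms: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = self.n_leaves
        if len(self.leaf_terms) != n:
            raise ValueError("leaf_terms length must equal n_leaves")
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges, got {len(self.merges)}")
        prev = -np.inf
        for k, (a, b, h) in enumerate(self.merges, start=1):
            created = n + k
            if not (1 <= a < created and 1 <= b < created and a != b):
                raise ValueError(f"merge {k}: children {a},{b} must be < created label {created}")
            if h < prev - 1e-12:
                raise ValueError(f"merge {k}: height {h} decreases below {prev}")
            prev = max(prev, h)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 1 if self.n_leaves > 1 else 1

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    def children(self, label: int) -> tuple[int, int] | None:
        """Children of an internal node; None for a leaf."""
        self._check_label(label)
        if label <= self.n_leaves:
            return None
        a, b, _ = self.merges[label - self.n_leaves - 1]
        return (a, b)

    def height(self, label: int) -> float:
        self._check_label(label)
        if label <= self.n_leaves:
            return 0.0
        return self.merges[label - self.n_leaves - 1][2]

    def leaves_under(self, label: int) -> list[int]:
        """Leaf labels under a node, ascending."""
        self._check_label(label)
        stack, leaves = [label], []
        while stack:
            node = stack.pop()
            if node <= self.n_leaves:
                leaves.append(node)
            else:
                a, b, _ = self.merges[node - self.n_leaves - 1]
                stack.extend((a, b))
        return sorted(leaves)

    def _check_label(self, label: int) -> None:
        if not (1 <= label <= self.n_nodes):
            raise ValueError(f"node label {label} outside 1..{self.n_nodes}")


def pairwise_distances(table: VectorTable, term_ids: Sequence[str]) -> np.ndarray:
    """Euclidean distance matrix over unit-norm term vectors.

    On unit vectors the Euclidean distance sqrt(2 - 2 cos) is a monotone
    transform of cosine distance, so the merge order is the same either way.
    """
    missing = [t for t in term_ids if t not in table.term_vectors]
    if missing:
        raise KeyError(f"term ids without vectors: {missing[:5]}")
    M = table.term_matrix(term_ids)
    sq = np.sum(M * M, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (M @ M.T)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def agglomerate_average_linkage(
    d: np.ndarray, leaf_terms: Sequence[str] | None = None
) -> MergeTree:
    """UPGMA agglomeration of a symmetric distance matrix.

    At each step the two active clusters with minimal average inter-cluster
    distance are merged at that distance. Ties are broken deterministically
    by the lexicographically smallest ``(min label, max label)`` pair.
    Averages are recomputed from the original matrix, never chained, so
    heights are exact cluster means.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items to agglomerate")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if leaf_terms is None:
        leaf_terms = [str(i) for i in range(1, n + 1)]
    if len(leaf_terms) != n:
        raise ValueError("leaf_terms length must match matrix size")

    labels = list(range(1, n + 1))
    members: dict[int, np.ndarray] = {i + 1: np.array([i]) for i in range(n)}
    # avg[i, j]: current average distance between active clusters i and j
    avg = d.copy()
    np.fill_diagonal(avg, np.inf)
    merges: list[tuple[int, int, float]] = []

    for k in range(1, n):
        m = len(labels)
        best = np.min(avg[:m, :m])
        ii, jj = np.where(avg[:m, :m] == best)
        pairs = [
            (min(labels[i], labels[j]), max(labels[i], labels[j]), i, j)
            for i, j in zip(ii, jj)
            if i < j
        ]
        la, lb, i, j = min(pairs)[0], min(pairs)[1], min(pairs)[2], min(pairs)[3]
        new_label = n + k
        merges.append((la, lb, float(best)))
        merged = np.sort(np.concatenate([members[la], members[lb]]))
        members[new_label] = merged

        # drop rows/cols i and j (j > i), append the new cluster
        keep = [x for x in range(m) if x not in (i, j)]
        labels = [labels[x] for x in keep] + [new_label]
        new_m = len(labels)
        new_avg = np.full((new_m, new_m), np.inf)
        new_avg[: new_m - 1, : new_m - 1] = avg[np.ix_(keep, keep)]
        for x, lab in enumerate(labels[:-1]):
            # canonical orientation (smaller label's members as rows) keeps
            # summation order, and hence floats, independent of merge history
            val = float(d[np.ix_(members[lab], merged)].mean())
            new_avg[x, new_m - 1] = new_avg[new_m - 1, x] = val
        avg = new_avg

    return MergeTree(n_leaves=n, leaf_terms=list(leaf_terms), merges=merges)


def branch_terms(tree: MergeTree, node: int) -> list[str]:
    """Terms at all leaves under ``node``, in leaf-label order."""
    return [tree.leaf_terms[leaf - 1] for leaf in tree.leaves_under(node)]


def cut_tree(tree: MergeTree, k: int) -> list[set[str]]:
    """Partition terms into ``k`` clusters by undoing the last k-1 merges."""
    if not (1 <= k <= tree.n_leaves):
        raise ValueError(f"k must be in 1..{tree.n_leaves}")
    # roots of the forest after suppressing the top k-1 merges
    suppressed_from = tree.n_leaves + (tree.n_leaves - 1) - (k - 1) + 1
    roots: set[int] = set()
    candidates = set(range(1, suppressed_from))
    for label in list(candidates):
        roots.add(label)
    for k_, (a, b, _) in enumerate(tree.merges, start=1):
        created = tree.n_leaves + k_
        if created < suppressed_from:
            roots.discard(a)
            roots.discard(b)
    roots = {r for r in roots if r < suppressed_from}
    return [set(branch_terms(tree, r)) for r in sorted(roots)]


def sample_branch_for_review(
    tree: MergeTree, node: int, budget: int, seed: int = 0
) -> list[str]:
    """Representative leaves of a branch for manual review.

    The branch is split recursively, deepest (highest) merges first, into at
    most ``budget`` subtrees, and one leaf is drawn per subtree; a reviewer
    can thus judge the whole branch while reading only a small fraction of
    its terms. Deterministic given ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    tree._check_label(node)
    frontier = [node]
    while len(frontier) < budget:
        internal = [f for f in frontier if f > tree.n_leaves]
        if not internal:
            break
        split = max(internal, key=tree.height)
        a, b, _ = tree.merges[split - tree.n_leaves - 1]
        frontier.remove(split)
        frontier.extend((a, b))
    rng = np.random.default_rng(seed)
    picked = []
    for sub in sorted(frontier):
        leaves = tree.leaves_under(sub)
        picked.append(leaves[int(rng.integers(len(leaves)))])
    return [tree.leaf_terms[leaf - 1] for leaf in sorted(set(picked))]


@dataclass(frozen=True)
class ClusterAnnotation:
    """A named cluster over one or more tree nodes (level 2 or 3)."""

    name: str
    node_labels: frozenset[int]
    level: int = 2

    def __post_init__(self) -> None:
        if self.level not in (2, 3):
            raise ValueError("level must be 2 or 3")
        if not self.node_labels:
            raise ValueError("node_labels must be non-empty")


class KOS:
    """A merge tree plus its curated cluster annotations.

    Level-2 annotations must be disjoint on terms; each may span several
    sibling branches (a paraphyletic union sharing one name). Every
    annotation event is recorded in an append-only log so a review session
    can be replayed.
    """

    def __init__(self, tree: MergeTree):
        self.tree = tree
        self.annotations: list[ClusterAnnotation] = []
        self.level3_parent: dict[str, str] = {}  # level-2 name -> level-3 name
        self.log: list[dict] = []
        self._term_owner: dict[str, str] = {}  # term -> level-2 annotation name

    def level2(self) -> list[ClusterAnnotation]:
        return [a for a in self.annotations if a.level == 2]

    def level3(self) -> list[ClusterAnnotation]:
        return [a for a in self.annotations if a.level == 3]

    def members(self, annotation: ClusterAnnotation) -> list[str]:
        """Union of leaf terms under the annotation's nodes, in leaf order."""
        seen: set[str] = set()
        out: list[str] = []
        for node in sorted(annotation.node_labels):
            for term in branch_terms(self.tree, node):
                if term not in seen:
                    seen.add(term)
                    out.append(term)
        return out

    def annotation_by_name(self, name: str, level: int = 2) -> ClusterAnnotation:
        for a in self.annotations:
            if a.name == name and a.level == level:
                return a
        raise KeyError(f"no level-{level} annotation named {name!r}")

    def term_cluster(self, term_id: str) -> str | None:
        """Name of the level-2 cluster owning a term, if any."""
        return self._term_owner.get(term_id)


def annotate_cluster(
    kos: KOS, node_labels: Iterable[int], name: str, level: int = 2
) -> KOS:
    """Append a named cluster annotation covering the given tree nodes.

    Level-2 annotations must not overlap on member terms; the error lists
    the conflicting terms.
    """
    labels = frozenset(int(x) for x in node_labels)
    ann = ClusterAnnotation(name=name, node_labels=labels, level=level)
    for label in labels:
        kos.tree._check_label(label)
    members = kos.members(ann)
    if level == 2:
        conflicts = {t: kos._term_owner[t] for t in members if t in kos._term_owner}
        if conflicts:
            raise ValueError(
                f"annotation {name!r} overlaps existing level-2 clusters on terms: "
                + ", ".join(f"{t} (in {o!r})" for t, o in sorted(conflicts.items()))
            )
        for t in members:
            kos._term_owner[t] = name
    kos.annotations.append(ann)
    kos.log.append(
        {"event": "annotate", "name": name, "level": level, "nodes": sorted(labels)}
    )
    return kos


def annotate_from_cut(kos: KOS, k: int, prefix: str = "cluster") -> KOS:
    """Annotate the k branches of a tree cut as provisional level-2 clusters.

    This is the automatic starting template a curator then renames/adjusts.
    """
    n = kos.tree.n_leaves
    # forest roots after undoing the top k-1 merges
    clusters = cut_tree(kos.tree, k)
    # map each cluster back to the tree node that spans exactly its terms
    term_to_leaf = {t: i + 1 for i, t in enumerate(kos.tree.leaf_terms)}
    node_of: dict[frozenset, int] = {}
    for label in range(1, kos.tree.n_nodes + 1):
        node_of[frozenset(branch_terms(kos.tree, label))] = label
    for idx, terms in enumerate(clusters, start=1):
        annotate_cluster(kos, {node_of[frozenset(terms)]}, f"{prefix}-{idx}", level=2)
    return kos


def cluster_representation(
    kos: KOS, annotation: ClusterAnnotation, table: VectorTable
) -> np.ndarray:
    """Componentwise mean of the member unit vectors (not re-normalized)."""
    members = kos.members(annotation)
    if not members:
        raise ValueError(f"annotation {annotation.name!r} has no member terms")
    return np.mean(table.term_matrix(members), axis=0)


def regroup_level3(
    kos: KOS,
    table: VectorTable,
    n_groups: int | None = None,
    names: Sequence[str] | None = None,
) -> KOS:
    """Re-cluster level-2 annotations into coarser named level-3 groups.

    An average-linkage tree is built over the level-2 cluster
    representations (mean member unit vectors) and cut into ``n_groups``
    groups (default: about one level-3 group per three level-2 clusters).
    Every level-2 annotation receives exactly one level-3 parent.
    """
    level2 = kos.level2()
    if len(level2) < 2:
        raise ValueError("regroup_level3 needs at least 2 level-2 annotations")
    reps = np.stack([cluster_representation(kos, a, table) for a in level2])
    sq = np.sum(reps * reps, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (reps @ reps.T), 0.0)
    np.fill_diagonal(d2, 0.0)
    meta = agglomerate_average_linkage(np.sqrt(d2), [a.name for a in level2])
    if n_groups is None:
        n_groups = max(2, round(len(level2) / 3))
    n_groups = min(n_groups, len(level2))
    groups = cut_tree(meta, n_groups)
    groups = sorted(groups, key=lambda g: min(g))
    if names is None:
        names = [f"level3-{i}" for i in range(1, len(groups) + 1)]
    if len(names) != len(groups):
        raise ValueError(f"need {len(groups)} level-3 names, got {len(names)}")
    by_name = {a.name: a for a in level2}
    for gname, group in zip(names, groups):
        nodes = frozenset().union(*(by_name[m].node_labels for m in group))
        kos.annotations.append(ClusterAnnotation(name=gname, node_labels=nodes, level=3))
        for m in group:
            kos.level3_parent[m] = gname
        kos.log.append({"event": "level3", "name": gname, "members": sorted(group)})
    return kos


def _pca_projector(X: np.ndarray) -> np.ndarray:
    """Default 2-D projector: principal components (deterministic)."""
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = u[:, :2] * s[:2]
    if coords.shape[1] < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    return coords


def layout_landscape(
    kos: KOS,
    table: VectorTable,
    citations_per_cluster: Mapping[str, float],
    projector: Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[dict]:
    """2-D landscape of the level-2 clusters.

    One record per level-2 cluster with 2-D coordinates of its
    representation vector, a dot area proportional to the summed citations
    of its articles, and a color key naming its level-3 parent. Clusters
    with no citation entry get area 0 with a warning.
    """
    level2 = kos.level2()
    if not level2:
        raise ValueError("no level-2 annotations to lay out")
    reps = np.stack([cluster_representation(kos, a, table) for a in level2])
    coords = (projector or _pca_projector)(reps)
    records = []
    for ann, (x, y) in zip(level2, np.asarray(coords)):
        if ann.name not in citations_per_cluster:
            warnings.warn(f"no citation total for cluster {ann.name!r}; using 0")
        cites = float(citations_per_cluster.get(ann.name, 0.0))
        records.append(
            {
                "name": ann.name,
                "x": float(x),
                "y": float(y),
                "area": cites,  # proportionality constant 1
                "color_key": kos.level3_parent.get(ann.name, ann.name),
            }
        )
    return records


# ---------------------------------------------------------------------------
# exports


def _newick(tree: MergeTree, node: int, parent_height: float) -> str:
    length = parent_height - tree.height(node)
    if node <= tree.n_leaves:
        safe = tree.leaf_terms[node - 1].replace(" ", "_").replace(",", "").replace("(", "").replace(")", "")
        return f"{safe}:{length:.10g}"
    a, b, h = tree.merges[node - tree.n_leaves - 1]
    return f"({_newick(tree, a, h)},{_newick(tree, b, h)}){node}:{length:.10g}"


def _indented(tree: MergeTree, node: int, depth: int, lines: list[str]) -> None:
    pad = "  " * depth
    if node <= tree.n_leaves:
        lines.append(f"{pad}{node}\t{tree.leaf_terms[node - 1]}")
    else:
        a, b, h = tree.merges[node - tree.n_leaves - 1]
        lines.append(f"{pad}{node}\t@{h:.10g}")
        _indented(tree, a, depth + 1, lines)
        _indented(tree, b, depth + 1, lines)


def export_tree(tree: MergeTree, format: str = "newick") -> str:
    """Serialize a tree as ``newick``, ``json`` or ``indented-text``.

    Newick branch lengths are height differences between a node and its
    parent; the JSON dump round-trips through :func:`tree_from_json`; the
    indented text lists all 2n-1 nodes, one per line, children indented
    under their parent.
    """
    if format == "newick":
        if tree.n_leaves == 1:
            return f"{tree.leaf_terms[0]};"
        root_h = tree.height(tree.root)
        a, b, _ = tree.merges[-1]
        return f"({_newick(tree, a, root_h)},{_newick(tree, b, root_h)}){tree.root};"
    if format == "json":
        return json.dumps(
            {
                "n_leaves": tree.n_leaves,
                "leaf_terms": tree.leaf_terms,
                "merges": [[a, b, h] for a, b, h in tree.merges],
            },
            sort_keys=True,
        )
    if format == "indented-text":
        lines: list[str] = []
        _indented(tree, tree.root, 0, lines)
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown tree format {format!r}")


def write_kos_tsv(kos: KOS, path) -> None:
    """Annotations as ``name<TAB>level<TAB>node_labels(comma-sep)`` rows.

    Level-3 parent links are recorded as extra ``parent`` rows.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tlevel\tnode_labels\n")
        for a in kos.annotations:
            fh.write(f"{a.name}\t{a.level}\t{','.join(map(str, sorted(a.node_labels)))}\n")
        for child, parent in sorted(kos.level3_parent.items()):
            fh.write(f"{child}\tparent\t{parent}\n")


def read_kos_tsv(tree: MergeTree, path) -> KOS:
    kos = KOS(tree)
    parents: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("name\t"):
            raise ValueError(f"KOS TSV {path} missing header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, level, rest = line.split("\t")
            if level == "parent":
                parents.append((name, rest))
            else:
                annotate_cluster(kos, (int(x) for x in rest.split(",")), name, int(level))
    for child, parent in parents:
        kos.level3_parent[child] = parent
    return kos


def tree_from_json(text: str) -> MergeTree:
    d = json.loads(text)
    return MergeTree(
        n_leaves=int(d["n_leaves"]),
        leaf_terms=list(d["leaf_terms"]),
        merges=[(int(a), int(b), float(h)) for a, b, h in d["merges"]],
    )
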