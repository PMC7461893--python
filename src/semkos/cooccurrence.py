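"""Citation-weighted keyword-cluster x method-cluster co-occurrence statistics.

For one article with citation weight W, keyword-cluster occurrence counts
K_1..K_m and method-cluster occurrence counts M_1..M_n, the correlation
index between keyword cluster i and method cluster j is

    C_ij = W * K_i * M_j / sum_{i,j} K_i * M_j

so the article distributes exactly its weight W over the cluster pairs it
combines (the denominator is (sum K)(sum M)). Summing C over all articles
gives the corpus-level correlation matrix; its log is drawn as a heat map
and the distribution of its cell values over the 10..400 range follows a
power law, fitted here by least squares in log-log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from semkos.lexicon_tokenizer import TokenStream
from semkos.tree_kos import KOS

__all__ = [
    "ArticleClusterCounts",
    "CorrelationMatrix",
    "PowerLawBins",
    "article_cluster_counts",
    "article_correlation",
    "aggregate_correlation",
    "log_heatmap_matrix",
    "rank_top_combinations",
    "bin_correlation_counts",
    "fit_power_law",
    "plot_heatmap",
]

BIN_LO = 10.0
BIN_HI = 400.0
BIN_STEP = 10.0


@dataclass
class ArticleClusterCounts:
    """Cluster-level token counts of one article plus its citation weight W."""

    article_id: str
    W: int
    K: dict[str, int] = field(default_factory=dict)  # keyword cluster -> count
    M: dict[str, int] = field(default_factory=dict)  # method cluster -> count

    def __post_init__(self) -> None:
        if self.W < 0:
            raise ValueError("W must be >= 0")
        if any(v < 1 for v in self.K.values()) or any(v < 1 for v in self.M.values()):
            raise ValueError("present cluster counts must be >= 1")


class CorrelationMatrix:
    """Non-negative keyword-cluster x method-cluster matrix (pandas-backed)."""

    def __init__(self, frame: pd.DataFrame):
        if (frame.values < 0).any():
            raise ValueError("correlation values must be >= 0")
        self.frame = frame

    @classmethod
    def zeros(cls, rows: Sequence[str], cols: Sequence[str]) -> "CorrelationMatrix":
        return cls(pd.DataFrame(0.0, index=list(rows), columns=list(cols)))

    @property
    def values(self) -> np.ndarray:
        return self.frame.values

    def total(self) -> float:
        return float(self.frame.values.sum())

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="keyword_cluster")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CorrelationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="keyword_cluster"))


def article_cluster_counts(
    stream: TokenStream, kwd_kos: KOS, mtd_kos: KOS, W: int
) -> ArticleClusterCounts:
    """Count token occurrences per level-2 cluster for one article.

    K counts keyword-term tokens by their owning keyword cluster, M method
    tokens by method cluster; tokens whose term is not covered by any
    level-2 annotation contribute nothing.
    """
    K: dict[str, int] = {}
    M: dict[str, int] = {}
    for tid in stream.term_ids():
        kc = kwd_kos.term_cluster(tid)
        if kc is not None:
            K[kc] = K.get(kc, 0) + 1
        mc = mtd_kos.term_cluster(tid)
        if mc is not None:
            M[mc] = M.get(mc, 0) + 1
    return ArticleClusterCounts(article_id=stream.article_id, W=W, K=K, M=M)


def article_correlation(
    counts: ArticleClusterCounts,
    rows: Sequence[str] | None = None,
    cols: Sequence[str] | None = None,
) -> CorrelationMatrix:
    """Per-article correlation-index matrix (one Eq.-style contribution).

    If either K or M is empty the article contributes a zero matrix;
    otherwise the cells sum to exactly W.
    """
    rows = list(rows) if rows is not None else sorted(counts.K)
    cols = list(cols) if cols is not None else sorted(counts.M)
    mat = CorrelationMatrix.zeros(rows, cols)
    if not counts.K or not counts.M:
        return mat
    denom = float(sum(counts.K.values())) * float(sum(counts.M.values()))
    for kc, ki in counts.K.items():
        if kc not in mat.frame.index:
            continue
        for mc, mj in counts.M.items():
            if mc not in mat.frame.columns:
                continue
            mat.frame.loc[kc, mc] = counts.W * ki * mj / denom
    return mat


def aggregate_correlation(contributions: Iterable[CorrelationMatrix]) -> CorrelationMatrix:
    """Elementwise sum of per-article matrices (shared dimensions required)."""
    contributions = list(contributions)
    if not contributions:
        return CorrelationMatrix.zeros([], [])
    first = contributions[0].frame
    acc = first.copy()
    for c in contributions[1:]:
        if not (c.frame.index.equals(first.index) and c.frame.columns.equals(first.columns)):
            raise ValueError("contribution dimensions do not match")
        acc = acc.add(c.frame)
    return CorrelationMatrix(acc)


def correlation_from_streams(
    streams: Sequence[TokenStream],
    kwd_kos: KOS,
    mtd_kos: KOS,
    citations: Mapping[str, int],
) -> CorrelationMatrix:
    """Aggregate correlation matrix of a corpus, over all level-2 clusters."""
    rows = sorted(a.name for a in kwd_kos.level2())
    cols = sorted(a.name for a in mtd_kos.level2())
    acc = CorrelationMatrix.zeros(rows, cols)
    for s in streams:
        counts = article_cluster_counts(s, kwd_kos, mtd_kos, int(citations.get(s.article_id, 0)))
        acc.frame += article_correlation(counts, rows, cols).frame
    return acc


def log_heatmap_matrix(matrix: CorrelationMatrix) -> np.ma.MaskedArray:
    """Natural log of positive cells; zero cells are masked, not -inf."""
    vals = matrix.values
    mask = vals <= 0
    with np.errstate(divide="ignore"):
        logs = np.where(mask, 0.0, np.log(np.where(mask, 1.0, vals)))
    return np.ma.MaskedArray(logs, mask=mask)


def rank_top_combinations(
    matrix: CorrelationMatrix, k: int
) -> list[tuple[str, str, float]]:
    """The k highest cells as (keyword cluster, method cluster, value), descending.

    Ties are broken by (row index, column index). k larger than the cell
    count returns all cells.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    frame = matrix.frame
    cells = [
        (float(frame.iat[i, j]), i, j)
        for i in range(frame.shape[0])
        for j in range(frame.shape[1])
    ]
    cells.sort(key=lambda c: (-c[0], c[1], c[2]))
    return [
        (frame.index[i], frame.columns[j], v) for v, i, j in cells[: min(k, len(cells))]
    ]


@dataclass
class PowerLawBins:
    """Cell-value histogram over [10, 400] at step 10 (39 bins).

    Bins are half-open [lo, lo+10) except the last, which is closed
    [390, 400] so that the inclusive upper end of the range is counted.
    Values below 10 or above 400 are discarded.
    """

    counts: np.ndarray
    lo: float = BIN_LO
    hi: float = BIN_HI
    step: float = BIN_STEP

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.n_bins,):
            raise ValueError(f"expected {self.n_bins} bin counts")
        if (self.counts < 0).any():
            raise ValueError("bin counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.step))

    def edges(self) -> np.ndarray:
        return self.lo + self.step * np.arange(self.n_bins + 1)

    def centers(self) -> np.ndarray:
        return self.lo + self.step * (np.arange(self.n_bins) + 0.5)

    def to_csv(self, path: str | Path) -> None:
        edges = self.edges()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("lo,hi,count\n")
            for i, c in enumerate(self.counts):
                fh.write(f"{edges[i]:g},{edges[i + 1]:g},{int(c)}\n")


def bin_correlation_counts(values: CorrelationMatrix | np.ndarray) -> PowerLawBins:
    """Histogram matrix cells (or raw values) into the 10..400 step-10 bins."""
    vals = values.values.ravel() if isinstance(values, CorrelationMatrix) else np.asarray(values, float).ravel()
    bins = PowerLawBins(np.zeros(39, dtype=int))
    edges = bins.edges()
    kept = vals[(vals >= bins.lo) & (vals <= bins.hi)]
    idx = np.minimum(((kept - bins.lo) // bins.step).astype(int), bins.n_bins - 1)
    counts = np.bincount(idx, minlength=bins.n_bins)
    return PowerLawBins(counts)


def fit_power_law(bins: PowerLawBins) -> tuple[float, float, float]:
    """Least-squares line on (log center, log count) over positive bins.

    Returns ``(exponent, intercept, r_squared)`` where the exponent is the
    magnitude of the fitted slope: counts ~ exp(intercept) * x**(-exponent).
    """
    pos = bins.counts > 0
    if pos.sum() < 3:
        raise ValueError("need at least 3 bins with positive counts to fit")
    x = np.log(bins.centers()[pos])
    y = np.log(bins.counts[pos].astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-slope), float(intercept), r2


def plot_heatmap(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Write the masked log heat map (rows = keyword clusters) to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    logm = log_heatmap_matrix(matrix)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(logm, aspect="auto", cmap="viridis")
    ax.set_xlabel("method clusters")
    ax.set_ylabel("keyword clusters")
    fig.colorbar(im, ax=ax, label="log correlation index")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
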