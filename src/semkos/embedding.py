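"""Joint term and document embeddings over token streams.

Terms that occur at least ``min_count`` times get a vector; every article
gets a document vector. Two interchangeable backends implement the narrow
contract (streams in, :class:`VectorTable` out):

``sgns`` (default)
    Count-weighted skip-gram with negative sampling, trained by full-batch
    gradient descent: windowed term-term co-occurrence counts weight the
    positive part of the objective and unigram^0.75 marginals the negative
    part, so one gradient step per epoch is equivalent in expectation to a
    pass of pairwise stochastic updates. Document vectors are trained
    distributed-bag-of-words style against the shared context matrix.
    The learning rate starts at ``initial_learning_rate`` and is reduced by
    ``learning_rate_decay_per_epoch`` every epoch (floored at 1e-4).

``ppmi_svd``
    Deterministic spectral embedding: positive pointwise mutual information
    of the same co-occurrence counts, factorized by truncated SVD. Document
    vectors are tf-weighted projections onto the term basis. Epochs and
    learning rate are ignored by this backend.

Both backends are deterministic given ``random_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from semkos.lexicon_tokenizer import TokenStream

__all__ = [
    "EmbeddingConfig",
    "VectorTable",
    "train_embeddings",
    "normalize_vectors",
    "learning_rate_at",
    "write_word2vec_text",
    "read_word2vec_text",
    "register_backend",
]

_LR_FLOOR = 1e-4
_NEGATIVE_SAMPLES = 5
_CONTEXT_SMOOTHING = 0.75


@dataclass(frozen=True)
class EmbeddingConfig:
    """Training hyperparameters (defaults follow the pipeline's reference run)."""

    window: int = 7
    dimension: int = 300
    min_count: int = 10
    epochs: int = 10
    initial_learning_rate: float = 0.025
    learning_rate_decay_per_epoch: float = 0.002
    train_word_vectors: bool = True
    random_seed: int = 0
    backend: str = "sgns"

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def learning_rate_at(config: EmbeddingConfig, epoch: int) -> float:
    """Learning rate used in epoch ``epoch`` (0-based), floored at 1e-4."""
    return max(
        config.initial_learning_rate - epoch * config.learning_rate_decay_per_epoch,
        _LR_FLOOR,
    )


@dataclass
class VectorTable:
    """Term and document vectors of one trained model (same dimension)."""

    term_vectors: dict[str, np.ndarray]
    doc_vectors: dict[str, np.ndarray]

    @property
    def dimension(self) -> int:
        for v in self.term_vectors.values():
            return int(v.shape[0])
        for v in self.doc_vectors.values():
            return int(v.shape[0])
        return 0

    def term_matrix(self, term_ids: Sequence[str]) -> np.ndarray:
        return np.stack([self.term_vectors[t] for t in term_ids])

    def doc_matrix(self, article_ids: Sequence[str]) -> np.ndarray:
        return np.stack([self.doc_vectors[a] for a in article_ids])


def _count_vocab(streams: Sequence[TokenStream], min_count: int) -> list[str]:
    counts: dict[str, int] = {}
    for s in streams:
        for tid in s.term_ids():
            counts[tid] = counts.get(tid, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError(
            f"no term occurs at least min_count={min_count} times in the streams; "
            "lower min_count or supply more text"
        )
    return vocab


def _cooccurrence_counts(
    streams: Sequence[TokenStream], vocab_index: dict[str, int], window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed symmetric term-term counts X and doc-term counts Y."""
    v = len(vocab_index)
    X = np.zeros((v, v))
    Y = np.zeros((len(streams), v))
    for d, stream in enumerate(streams):
        ids = [vocab_index[t] for t in stream.term_ids() if t in vocab_index]
        n = len(ids)
        for i, ci in enumerate(ids):
            Y[d, ci] += 1.0
            for j in range(max(0, i - window), i):
                X[ci, ids[j]] += 1.0
                X[ids[j], ci] += 1.0
    return X, Y


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


_STEPS_PER_EPOCH = 50
_DOC_STEPS_PER_EPOCH = 10


def _train_sgns(
    X: np.ndarray, Y: np.ndarray, config: EmbeddingConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Full-batch descent on the count-weighted skip-gram objective.

    Positive pairs are weighted by the row-stochastic co-occurrence
    distribution of each center term; the negative part puts
    ``_NEGATIVE_SAMPLES`` units of mass per center on the unigram^0.75
    context distribution. An epoch performs ``_STEPS_PER_EPOCH`` gradient
    steps at that epoch's learning rate, standing in for one pass of
    pairwise stochastic updates.
    """
    rng = np.random.default_rng(config.random_seed)
    v, d = X.shape[0], config.dimension
    bound = 0.5 / d
    U = rng.uniform(-bound, bound, size=(v, d))  # center (term) vectors
    V = rng.uniform(-bound, bound, size=(v, d))  # context vectors
    D = rng.uniform(-bound, bound, size=(Y.shape[0], d))  # doc vectors

    row = np.maximum(X.sum(axis=1, keepdims=True), 1.0)
    P = X / row  # row-stochastic positives
    q = X.sum(axis=0) ** _CONTEXT_SMOOTHING
    q = q / q.sum() if q.sum() > 0 else np.full(v, 1.0 / v)
    neg = _NEGATIVE_SAMPLES * q[None, :]

    if config.train_word_vectors:
        for epoch in range(config.epochs):
            lr = learning_rate_at(config, epoch)
            for _ in range(_STEPS_PER_EPOCH):
                S = _sigmoid(U @ V.T)
                G = (S - 1.0) * P + S * neg
                U_new = U - lr * (G @ V)
                V = V - lr * (G.T @ U)
                U = U_new

    # distributed-bag-of-words style: the doc vector predicts its terms
    # against the (now frozen) context matrix
    doc_len = np.maximum(Y.sum(axis=1, keepdims=True), 1.0)
    Pd = Y / doc_len
    for epoch in range(config.epochs):
        lr = learning_rate_at(config, epoch)
        for _ in range(_DOC_STEPS_PER_EPOCH):
            S = _sigmoid(D @ V.T)
            D = D - lr * (((S - 1.0) * Pd + S * neg) @ V)
    return U, D


def _train_ppmi_svd(
    X: np.ndarray, Y: np.ndarray, config: EmbeddingConfig
) -> tuple[np.ndarray, np.ndarray]:
    total = X.sum()
    v = X.shape[0]
    if total == 0:
        rng = np.random.default_rng(config.random_seed)
        U = rng.uniform(-0.5, 0.5, size=(v, config.dimension))
        return U, Y @ U
    row = X.sum(axis=1, keepdims=True)
    col = X.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log((X * total) / (row @ col))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)
    k = min(config.dimension, v)
    # deterministic dense SVD on the (small) vocabulary-sized matrix
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    U = u[:, :k] * np.sqrt(s[:k])
    if k < config.dimension:
        U = np.pad(U, ((0, 0), (0, config.dimension - k)))
    # docs: tf-weighted mean of term vectors in the same space
    lengths = np.maximum(Y.sum(axis=1, keepdims=True), 1.0)
    D = (Y / lengths) @ U
    return U, D


_BACKENDS: dict[str, Callable] = {
    "sgns": _train_sgns,
    "ppmi_svd": _train_ppmi_svd,
}


def register_backend(name: str, trainer: Callable) -> None:
    """Register an alternative trainer ``(X, Y, config) -> (U, D)``."""
    _BACKENDS[name] = trainer


def train_embeddings(
    streams: Sequence[TokenStream], config: EmbeddingConfig | None = None
) -> VectorTable:
    """Train term and document vectors on tokenized article streams.

    A vector is produced for every term occurring at least ``min_count``
    times in total, and for every article. Fixed seed gives a reproducible
    table.
    """
    if not streams:
        raise ValueError("streams must be non-empty")
    config = config or EmbeddingConfig()
    if config.backend not in _BACKENDS:
        raise ValueError(f"unknown backend {config.backend!r}; have {sorted(_BACKENDS)}")
    vocab = _count_vocab(streams, config.min_count)
    vocab_index = {t: i for i, t in enumerate(vocab)}
    X, Y = _cooccurrence_counts(streams, vocab_index, config.window)
    U, D = _BACKENDS[config.backend](X, Y, config)
    return VectorTable(
        term_vectors={t: U[i].copy() for t, i in vocab_index.items()},
        doc_vectors={s.article_id: D[d].copy() for d, s in enumerate(streams)},
    )


def normalize_vectors(table: VectorTable) -> VectorTable:
    """Scale every term vector to unit Euclidean norm; doc vectors untouched."""
    normed = {}
    for tid, vec in table.term_vectors.items():
        norm = float(np.linalg.norm(vec))
        if norm == 0.0:
            raise ValueError(f"term {tid!r} has a zero-norm vector; cannot normalize")
        normed[tid] = vec / norm
    return VectorTable(term_vectors=normed, doc_vectors=dict(table.doc_vectors))


# ---------------------------------------------------------------------------
# word2vec text format


def write_word2vec_text(vectors: dict[str, np.ndarray], path: str | Path) -> None:
    """``count dim`` header then one ``id v1..vd`` line per vector."""
    items = sorted(vectors.items())
    dim = items[0][1].shape[0] if items else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(items)} {dim}\n")
        for key, vec in items:
            fh.write(key + " " + " ".join(f"{x:.17g}" for x in vec) + "\n")


def read_word2vec_text(path: str | Path) -> dict[str, np.ndarray]:
    with open(path, encoding="utf-8") as fh:
        count, dim = (int(x) for x in fh.readline().split())
        out: dict[str, np.ndarray] = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"malformed vector line in {path}")
            out[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(out) != count:
        raise ValueError(f"{path}: header promised {count} vectors, found {len(out)}")
    return out
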