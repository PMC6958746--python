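"""Skip-gram context embeddings for words and class identifiers.

The trainer learns input ("word") and output ("context") vectors with
skip-gram negative sampling over (center, context) pairs within a symmetric
window; after normalization of class mentions, class identifiers are
embedded exactly like ordinary words.  ``skipgram_objective`` evaluates the
exact average log softmax probability of all context tokens given their
centers by full enumeration — tractable only for small vocabularies, which
is precisely its role as a test oracle for the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .text import AnnotatedCorpus


@dataclass
class EmbeddingConfig:
    """Skip-gram hyperparameters.

    Defaults follow the conventional word2vec settings: 100 dimensions,
    window 5, minimum occurrence count 5.
    """

    dim: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 5
    seed: int = 0
    negatives: int = 5
    learning_rate: float = 0.1
    batch_size: int = 2048

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class EmbeddingMatrix:
    """One vector per vocabulary item, in a fixed deterministic order."""

    vocab: list[str]
    vectors: np.ndarray
    context_vectors: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.vocab) != len(self.vectors):
            raise ValueError("vocab/vectors length mismatch")
        self._index = {t: i for i, t in enumerate(self.vocab)}
        if len(self._index) != len(self.vocab):
            raise ValueError("duplicate tokens in vocab")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.vocab)

    def get_vector(self, token: str) -> np.ndarray | None:
        """Vector for an in-vocab token, else None (absence is not an error)."""
        i = self._index.get(token)
        return None if i is None else self.vectors[i]

    def index(self, token: str) -> int | None:
        return self._index.get(token)


class ObjectiveResult(NamedTuple):
    """Exact corpus-average log probability and pair bookkeeping."""

    value: float
    n_pairs: int
    n_skipped_tokens: int


def build_vocab(corpus: AnnotatedCorpus, min_count: int) -> list[str]:
    """Tokens occurring at least ``min_count`` times, ordered by descending
    frequency then lexicographically (deterministic)."""
    counts: dict[str, int] = {}
    for stream in corpus.token_streams():
        for t in stream:
            counts[t] = counts.get(t, 0) + 1
    kept = [t for t, c in counts.items() if c >= min_count]
    kept.sort(key=lambda t: (-counts[t], t))
    return kept


def _pairs(corpus: AnnotatedCorpus, index: dict[str, int], window: int,
           ) -> tuple[np.ndarray, int]:
    """All in-vocab (center, context) index pairs within the window.

    Windows do not cross document boundaries.  Out-of-vocab tokens are
    transparent to neither side: they are skipped entirely (counted)."""
    centers: list[int] = []
    contexts: list[int] = []
    skipped = 0
    for stream in corpus.token_streams():
        idx = []
        for t in stream:
            j = index.get(t)
            if j is None:
                skipped += 1
            else:
                idx.append(j)
        n = len(idx)
        for i in range(n):
            lo = max(0, i - window)
            hi = min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(idx[i])
                    contexts.append(idx[j])
    if not centers:
        return np.empty((0, 2), dtype=np.int64), skipped
    return np.stack([np.asarray(centers, dtype=np.int64),
                     np.asarray(contexts, dtype=np.int64)], axis=1), skipped


def train_skipgram(corpus: AnnotatedCorpus,
                   cfg: EmbeddingConfig = EmbeddingConfig(),
                   ) -> EmbeddingMatrix:
    """Train skip-gram embeddings with negative sampling.

    Single-threaded and fully deterministic for a fixed seed: vocabulary
    order, initialization, pair shuffling and negative draws all come from
    one seeded generator.  Input vectors start uniform in ±0.5/dim and
    context vectors at zero (so the initial predictive distribution is
    exactly uniform).  Gradients are accumulated per mini-batch and applied
    with Adagrad, which keeps per-element steps bounded no matter how many
    times a frequent token repeats within one batch.
    """
    vocab = build_vocab(corpus, cfg.min_count)
    if not vocab:
        raise ValueError(
            f"no token reaches min_count={cfg.min_count}; vocabulary is empty"
        )
    index = {t: i for i, t in enumerate(vocab)}
    pairs, _ = _pairs(corpus, index, cfg.window)
    V, d = len(vocab), cfg.dim
    rng = np.random.default_rng(cfg.seed)
    W = rng.uniform(-0.5 / d, 0.5 / d, size=(V, d))
    C = np.zeros((V, d))

    # unigram^0.75 negative-sampling distribution (as inverse CDF)
    counts = np.zeros(V)
    for stream in corpus.token_streams():
        for t in stream:
            i = index.get(t)
            if i is not None:
                counts[i] += 1
    noise = counts ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    col = np.arange(d, dtype=np.int64)

    def gradient_sum(rows: np.ndarray, values: np.ndarray) -> np.ndarray:
        # grouped accumulation via a flattened bincount: much faster than
        # np.add.at for large batches with repeated indices
        flat = (rows[:, None] * d + col).ravel()
        return np.bincount(flat, weights=values.ravel(),
                           minlength=V * d).reshape(V, d)

    n_pairs = len(pairs)
    if n_pairs:
        gsq_W = np.zeros((V, d))
        gsq_C = np.zeros((V, d))
        eps = 1e-8
        for _ in range(cfg.epochs):
            order = rng.permutation(n_pairs)
            for s in range(0, n_pairs, cfg.batch_size):
                batch = pairs[order[s : s + cfg.batch_size]]
                c_idx, o_idx = batch[:, 0], batch[:, 1]
                neg = np.searchsorted(
                    noise_cdf, rng.random((len(batch), cfg.negatives)))
                h = W[c_idx]                           # (B, d)
                # positive pairs: label 1
                s_pos = np.einsum("bd,bd->b", h, C[o_idx])
                g_pos = _sigmoid(s_pos) - 1.0          # (B,)
                # negative pairs: label 0
                s_neg = np.einsum("bd,bkd->bk", h, C[neg])
                g_neg = _sigmoid(s_neg)                # (B, k)
                grad_h = (g_pos[:, None] * C[o_idx]
                          + np.einsum("bk,bkd->bd", g_neg, C[neg]))
                ctx_rows = np.concatenate([o_idx, neg.ravel()])
                ctx_vals = np.concatenate(
                    [g_pos[:, None] * h,
                     (g_neg[:, :, None] * h[:, None, :]).reshape(-1, d)])
                g_C = gradient_sum(ctx_rows, ctx_vals)
                g_W = gradient_sum(c_idx, grad_h)
                gsq_C += g_C * g_C
                gsq_W += g_W * g_W
                C -= cfg.learning_rate * g_C / (np.sqrt(gsq_C) + eps)
                W -= cfg.learning_rate * g_W / (np.sqrt(gsq_W) + eps)
    return EmbeddingMatrix(vocab=vocab, vectors=W, context_vectors=C)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def skipgram_objective(corpus: AnnotatedCorpus,
                       emb: EmbeddingMatrix,
                       context_vectors: np.ndarray,
                       window: int) -> ObjectiveResult:
    """Exact skip-gram objective: average log softmax probability.

    Enumerates every (center, context) pair with the given window and
    computes ``mean log p(context | center)`` under the full softmax over
    the vocabulary — the quantity negative sampling approximates.  Intended
    for small vocabularies (full V x V softmax).  Out-of-vocab tokens are
    skipped and counted.  The value is <= 0, with equality only when the
    vocabulary has a single item.
    """
    index = {t: i for i, t in enumerate(emb.vocab)}
    pairs, skipped = _pairs(corpus, index, window)
    if len(pairs) == 0:
        return ObjectiveResult(0.0, 0, skipped)
    scores = emb.vectors @ np.asarray(context_vectors).T      # (V, V)
    m = scores.max(axis=1, keepdims=True)
    log_z = m.squeeze(1) + np.log(np.exp(scores - m).sum(axis=1))
    log_p = scores[pairs[:, 0], pairs[:, 1]] - log_z[pairs[:, 0]]
    return ObjectiveResult(float(log_p.mean()), len(pairs), skipped)


def project_2d(emb: EmbeddingMatrix,
               groups: dict[str, str] | None = None,
               seed: int = 0,
               path: str | Path | None = None) -> dict[str, np.ndarray]:
    """t-SNE projection of the embedding to 2-d, optionally plotted.

    Deterministic for a fixed seed; perplexity is clamped for tiny inputs.
    When ``path`` is given a scatter plot with one color per group is saved.
    """
    from sklearn.manifold import TSNE

    n = len(emb.vocab)
    if n < 2:
        raise ValueError("projection needs at least 2 tokens")
    perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
    X = np.asarray(emb.vectors, dtype=np.float64)
    coords = TSNE(n_components=2, perplexity=perplexity, init="random",
                  random_state=seed).fit_transform(X)
    result = {t: coords[i] for i, t in enumerate(emb.vocab)}
    if path is not None:
        _plot_projection(result, groups or {}, path)
    return result


def _plot_projection(coords: dict[str, np.ndarray],
                     groups: dict[str, str],
                     path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted({groups.get(t, "other") for t in coords})
    fig, ax = plt.subplots(figsize=(6, 6))
    for lab in labels:
        pts = np.array([xy for t, xy in coords.items()
                        if groups.get(t, "other") == lab])
        ax.scatter(pts[:, 0], pts[:, 1], s=8, label=lab)
    ax.legend(fontsize="small")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_word2vec_text(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Write the embedding in word2vec text format ('V D' header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb.vocab)} {emb.dim}\n")
        for tok, vec in zip(emb.vocab, emb.vectors):
            fh.write(tok + " " + " ".join(f"{v:.6f}" for v in vec) + "\n")


def load_word2vec_text(path: str | Path) -> EmbeddingMatrix:
    """Read an embedding written by :func:`save_word2vec_text`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        n, d = int(header[0]), int(header[1])
        vocab: list[str] = []
        vecs = np.empty((n, d))
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            vocab.append(parts[0])
            vecs[i] = [float(x) for x in parts[1 : d + 1]]
    return EmbeddingMatrix(vocab=vocab, vectors=vecs)
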