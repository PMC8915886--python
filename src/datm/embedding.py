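"""Word embeddings defining the semantic space.

Words are mapped to points in an N-dimensional space such that words used in
similar contexts land nearby.  Training uses a minimal, single-threaded
skip-gram-with-negative-sampling (SGNS) trainer written on numpy: for each
(center, context) pair within a symmetric window, the model pushes the pair's
vectors together and pushes the center away from ``neg`` noise words drawn
from the unigram distribution raised to the 3/4 power.  Single-threaded,
seeded training is bitwise reproducible.

Vectors interoperate with the word2vec text format ("V N" header, one
``term v1 ... vN`` line per word), so externally trained embeddings can be
loaded in place of the built-in trainer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Document, Vocabulary

__all__ = ["Embedding", "train_embedding", "cosine", "nearest_words"]


@dataclass
class Embedding:
    """A vocabulary plus its V x N matrix of word vectors (row order = vocab order)."""

    vocab: Vocabulary
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.vocab):
            raise ValueError("vectors must be V x N with V = vocabulary size")
        if self.vectors.shape[1] < 2:
            raise ValueError("embedding dimension must be >= 2")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vectors contain NaN or Inf")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self.vocab.index[term]]

    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy (the dictionary-learning input convention)."""
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot normalize zero word vectors")
        return self.vectors / norms

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocab)} {self.dim}\n")
            for term, row in zip(self.vocab.terms, self.vectors):
                fh.write(term + " " + " ".join(f"{x:.17g}" for x in row) + "\n")

    @classmethod
    def load(cls, path: str | Path, vocab: Vocabulary | None = None) -> "Embedding":
        """Load word2vec-text vectors; if ``vocab`` is None, counts default to 1.

        With a vocabulary given, rows are reordered to the vocabulary's term
        order and every vocabulary term must be present in the file.
        """
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            v, n = int(header[0]), int(header[1])
            terms, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                terms.append(parts[0])
                rows.append([float(x) for x in parts[1 : n + 1]])
        if len(terms) != v:
            raise ValueError("vector file header inconsistent with line count")
        mat = np.asarray(rows, dtype=np.float64)
        if vocab is None:
            vocab = Vocabulary(terms, np.ones(len(terms), dtype=np.int64))
            return cls(vocab, mat)
        lookup = {t: i for i, t in enumerate(terms)}
        missing = [t for t in vocab.terms if t not in lookup]
        if missing:
            raise ValueError(f"vector file lacks vocabulary terms, e.g. {missing[:5]}")
        order = [lookup[t] for t in vocab.terms]
        return cls(vocab, mat[order])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _skipgram_pairs(doc_ids: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for ids in doc_ids:
        L = len(ids)
        if L < 2:
            continue
        for off in range(1, window + 1):
            if L <= off:
                break
            centers.append(ids[:-off])
            contexts.append(ids[off:])
            # symmetric pair (context predicts center too)
            centers.append(ids[off:])
            contexts.append(ids[:-off])
    if not centers:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def train_embedding(
    docs: list[Document],
    vocab: Vocabulary,
    dim: int = 100,
    window: int = 5,
    epochs: int = 5,
    seed: int = 0,
    neg: int = 5,
    lr: float = 0.05,
    batch: int = 1024,
) -> Embedding:
    """Train SGNS vectors on the documents (out-of-vocabulary tokens dropped).

    The learning rate decays linearly from ``lr`` to ``lr/100`` over all
    updates.  Negative words are drawn from p(w)^0.75.  Deterministic given
    the seed (single-threaded throughout).
    """
    if dim <= 1:
        raise ValueError("embedding dimension must be >= 2")
    if epochs < 1 or window < 1:
        raise ValueError("epochs and window must be >= 1")
    doc_ids = [
        np.array([vocab.index[t] for t in d.tokens if t in vocab.index], dtype=np.int64)
        for d in docs
    ]
    if sum(len(a) for a in doc_ids) == 0:
        raise ValueError("no in-vocabulary tokens to train on")
    centers, contexts = _skipgram_pairs(doc_ids, window)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("corpus has no co-occurrence pairs (documents too short)")

    V = len(vocab)
    rng = np.random.default_rng(seed)
    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))

    noise = vocab.p**0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    total = epochs * n_pairs
    done = 0
    min_lr = lr / 100.0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            idx = order[start : start + batch]
            c = centers[idx]
            o = contexts[idx]
            B = len(idx)
            negs = np.searchsorted(noise_cdf, rng.random((B, neg)))
            # targets: positive context then negatives; labels 1, 0...
            tgt = np.concatenate([o[:, None], negs], axis=1)  # B x (1+neg)
            vc = w_in[c]  # B x d
            vt = w_out[tgt]  # B x (1+neg) x d
            score = _sigmoid(np.einsum("bd,bkd->bk", vc, vt))
            score[:, 0] -= 1.0  # gradient of -log sigma for the positive
            step = lr + (min_lr - lr) * (done / total)
            g_c = np.einsum("bk,bkd->bd", score, vt)
            g_t = score[:, :, None] * vc[:, None, :]
            np.add.at(w_in, c, -step * g_c)
            np.add.at(w_out, tgt.ravel(), -step * g_t.reshape(-1, dim))
            done += B
    return Embedding(vocab, w_in)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; raises on zero vectors rather than returning NaN."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def nearest_words(q: np.ndarray, emb: Embedding, n: int = 25) -> list[tuple[str, float]]:
    """The ``n`` vocabulary terms with highest cosine to ``q``.

    Descending cosine; ties broken by ascending vocabulary index.
    """
    q = np.asarray(q, dtype=np.float64)
    nq = np.linalg.norm(q)
    if nq == 0:
        raise ValueError("zero query vector")
    if n > len(emb.vocab):
        raise ValueError("n exceeds vocabulary size")
    norms = np.linalg.norm(emb.vectors, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    cos = (emb.vectors @ q) / (safe * nq)
    cos[norms == 0] = -np.inf
    order = np.lexsort((np.arange(len(cos)), -cos))[:n]
    return [(emb.vocab.terms[i], float(cos[i])) for i in order]
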