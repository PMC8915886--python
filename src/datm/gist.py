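"""From observed word sequences to points in semantic space and topics.

Under the latent-variable language model, the probability of emitting word w
at position t mixes the word's corpus frequency p(w) with a log-linear term
in the inner product between its vector and the combined context
c̃t = β·c0 + (1−β)·ct, where c0 is a corpus-wide global component and ct is
the slowly drifting local gist.  The MAP estimate of c̃t for a window C of
observed words is the smooth-inverse-frequency (SIF) weighted sum

    c̃t ≈ Σ_{w in C} a / (p(w) + a) · w,

with a single smoothing constant ``a``.  Subtracting the projection onto c0
(the first principal component of a sample of window embeddings) leaves the
local gist, which is assigned to its nearest discourse atom by cosine.
Rolling windows over a document yield its topic sequence, distribution and
binary presence vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atoms import AtomDictionary
from .corpus import Document
from .embedding import Embedding

__all__ = [
    "NO_TOPIC",
    "SIFConfig",
    "TopicRecord",
    "sif_weight",
    "map_context",
    "estimate_global",
    "remove_global",
    "corpus_global_vector",
    "window_bounds",
    "assign_topic",
    "document_topics",
    "records_to_frame",
    "frame_to_records",
]

#: Sentinel topic id for windows whose gist is zero (e.g. all tokens out of
#: vocabulary); excluded from distributions and presence.
NO_TOPIC = -1


@dataclass
class SIFConfig:
    """Smoothing weight and rolling-window geometry.

    ``a`` is the SIF constant a = (1−α)/(αZ) collapsed into one tunable;
    windows of ``window_size`` tokens advance by ``stride`` tokens.
    """

    a: float = 1e-3
    window_size: int = 10
    stride: int = 5

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("SIF weight a must be positive")
        if self.window_size < 1 or self.stride < 1:
            raise ValueError("window_size and stride must be >= 1")


@dataclass
class TopicRecord:
    """Per-document topic sequence, distribution and binary presence."""

    doc_id: str
    sequence: list[int]
    distribution: np.ndarray
    presence: np.ndarray
    n_windows: int = 0
    n_oov_tokens: int = 0
    metadata: dict = field(default_factory=dict)


def sif_weight(p_w: float, a: float) -> float:
    """Smooth inverse frequency weight a/(p(w)+a): near 1 for rare words,
    decreasing toward 0 for frequent ones."""
    if a <= 0:
        raise ValueError("a must be positive")
    if not 0 <= p_w <= 1:
        raise ValueError("p_w must be a probability")
    return a / (p_w + a)


def map_context(
    window: list[str], emb: Embedding, cfg: SIFConfig
) -> tuple[np.ndarray, int]:
    """MAP estimate of the combined context vector for one window.

    Returns the SIF-weighted sum over in-vocabulary tokens and the number of
    out-of-vocabulary tokens skipped.  A window with no in-vocabulary tokens
    yields a zero vector (flagged by the caller), not an exception.
    """
    vec = np.zeros(emb.dim)
    oov = 0
    for t in window:
        i = emb.vocab.index.get(t)
        if i is None:
            oov += 1
            continue
        vec += sif_weight(float(emb.vocab.p[i]), cfg.a) * emb.vectors[i]
    return vec, oov


def estimate_global(contexts: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """First right singular vector of the stacked (uncentered) context matrix.

    Sign is fixed so the largest-|entry| coordinate is positive, making the
    estimate reproducible across SVD implementations.
    """
    M = np.asarray(contexts, dtype=np.float64)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need at least 2 context vectors")
    if not np.any(M):
        raise ValueError("all context vectors are zero")
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    c0 = vt[0]
    if c0[np.argmax(np.abs(c0))] < 0:
        c0 = -c0
    return c0


def remove_global(c_tilde: np.ndarray, c0: np.ndarray) -> np.ndarray:
    """Project out the global component: ct = c̃ − ⟨c̃, c0⟩·c0."""
    if abs(np.linalg.norm(c0) - 1.0) > 1e-8:
        raise ValueError("c0 must be unit-norm")
    return c_tilde - (c_tilde @ c0) * c0


def window_bounds(tokens: list[str], cfg: SIFConfig, in_vocab) -> list[tuple[int, int]]:
    """(start, end) token spans of the rolling windows of a document.

    Full windows start at every multiple of ``stride``; a document shorter
    than one window is a single span; a trailing partial window is kept only
    if it has at least ceil(window_size/2) in-vocabulary tokens."""
    L = len(tokens)
    w, s = cfg.window_size, cfg.stride
    if L == 0:
        return []
    if L <= w:
        return [(0, L)]
    starts = list(range(0, L - w + 1, s))
    bounds = [(i, i + w) for i in starts]
    if starts[-1] + w < L:
        tail_start = starts[-1] + s
        if sum(1 for t in tokens[tail_start:] if in_vocab(t)) >= math.ceil(w / 2):
            bounds.append((tail_start, L))
    return bounds


def _doc_windows(tokens: list[str], cfg: SIFConfig, in_vocab) -> list[list[str]]:
    return [tokens[a:b] for a, b in window_bounds(tokens, cfg, in_vocab)]


def corpus_global_vector(
    docs: list[Document],
    emb: Embedding,
    cfg: SIFConfig,
    max_windows: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Estimate c0 from a seeded random sample of context-window embeddings."""
    embeds = []
    for d in docs:
        for win in _doc_windows(d.tokens, cfg, emb.vocab.index.__contains__):
            v, _ = map_context(win, emb, cfg)
            if np.any(v):
                embeds.append(v)
    if len(embeds) < 2:
        raise ValueError("not enough non-empty windows to estimate the global vector")
    M = np.stack(embeds)
    if len(M) > max_windows:
        rng = np.random.default_rng(seed)
        M = M[rng.choice(len(M), size=max_windows, replace=False)]
    return estimate_global(M)


def assign_topic(ct: np.ndarray, dct: AtomDictionary) -> tuple[int, float]:
    """Nearest atom by cosine; ties go to the lowest topic id; zero gist
    yields the NO_TOPIC sentinel."""
    if dct.K < 1:
        raise ValueError("empty dictionary")
    n = np.linalg.norm(ct)
    if n == 0:
        return NO_TOPIC, 0.0
    cos = dct.atoms @ (ct / n)  # atoms are unit-norm
    k = int(np.argmax(cos))  # argmax returns the first (lowest id) maximizer
    return k, float(cos[k])


def document_topics(
    doc: Document,
    emb: Embedding,
    dct: AtomDictionary,
    cfg: SIFConfig,
    c0: np.ndarray,
) -> TopicRecord:
    """Assign every rolling window of a document to its nearest atom.

    Zero-gist windows carry the sentinel id in the sequence but are excluded
    from the distribution and presence.  A document with no in-vocabulary
    tokens gets an empty sequence and all-zero presence.
    """
    seq: list[int] = []
    oov_total = 0
    for win in _doc_windows(doc.tokens, cfg, emb.vocab.index.__contains__):
        v, oov = map_context(win, emb, cfg)
        oov_total += oov
        ct = remove_global(v, c0)
        k, _ = assign_topic(ct, dct)
        seq.append(k)
    valid = [k for k in seq if k != NO_TOPIC]
    dist = np.zeros(dct.K)
    presence = np.zeros(dct.K, dtype=np.int64)
    if valid:
        ids, counts = np.unique(valid, return_counts=True)
        dist[ids] = counts / counts.sum()
        presence[ids] = 1
    return TopicRecord(
        doc_id=doc.doc_id,
        sequence=seq,
        distribution=dist,
        presence=presence,
        n_windows=len(seq),
        n_oov_tokens=oov_total,
        metadata=doc.metadata,
    )


def records_to_frame(records: list[TopicRecord]) -> pd.DataFrame:
    """One row per document: doc_id, comma-joined sequence, K presence columns."""
    if not records:
        raise ValueError("no records")
    K = len(records[0].presence)
    rows = []
    for r in records:
        row = {"doc_id": r.doc_id, "sequence": ",".join(str(k) for k in r.sequence)}
        for k in range(K):
            row[f"topic_{k}"] = int(r.presence[k])
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[TopicRecord]:
    """Inverse of :func:`records_to_frame` (distribution recomputed from the sequence)."""
    topic_cols = [c for c in df.columns if c.startswith("topic_")]
    K = len(topic_cols)
    records = []
    for _, row in df.iterrows():
        seq_str = row["sequence"]
        if seq_str in ("", None) or (isinstance(seq_str, float) and pd.isna(seq_str)):
            seq = []
        else:
            # a fully numeric column may have been parsed as float ("0.0")
            seq = [int(float(x)) for x in str(seq_str).split(",")]
        valid = [k for k in seq if k != NO_TOPIC]
        dist = np.zeros(K)
        presence = np.zeros(K, dtype=np.int64)
        if valid:
            ids, counts = np.unique(valid, return_counts=True)
            dist[ids] = counts / counts.sum()
            presence[ids] = 1
        records.append(
            TopicRecord(
                doc_id=str(row["doc_id"]),
                sequence=seq,
                distribution=dist,
                presence=presence,
                n_windows=len(seq),
            )
        )
    return records
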