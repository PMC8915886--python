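"""Corpus handling: loading, tokenization, phrase merging, vocabulary.

A corpus is a plain-text file with one document (record narrative) per line,
optionally joined with a delimited metadata table keyed by ``doc_id``.
Frequently co-occurring adjacent token pairs are merged into single
underscore-joined terms before the vocabulary and unigram probabilities
``p(w)`` are computed, so that the probabilities match the terms actually
embedded downstream.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Document",
    "Vocabulary",
    "tokenize",
    "load_corpus",
    "save_corpus",
    "merge_phrases",
    "build_vocabulary",
]

# Tokenization rule: lowercase, then keep runs of [a-z0-9_'] — punctuation is
# stripped but underscores survive so merged phrases stay single terms.
_TOKEN_RE = re.compile(r"[a-z0-9_']+")


@dataclass
class Document:
    """One record: an id, its token sequence, and covariate metadata."""

    doc_id: str
    tokens: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return len(self.tokens) == 0


class Vocabulary:
    """Ordered term list with counts and unigram probabilities p(w)."""

    def __init__(self, terms: list[str], counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if len(terms) != len(counts):
            raise ValueError("terms and counts length mismatch")
        if len(terms) == 0:
            raise ValueError("empty vocabulary")
        if np.any(counts <= 0):
            raise ValueError("all vocabulary counts must be positive")
        self.terms = list(terms)
        self.counts = counts
        self.p = counts / counts.sum()
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def prob(self, term: str) -> float:
        return float(self.p[self.index[term]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "count": self.counts, "p": self.p})

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        df = pd.read_csv(path, sep="\t")
        return cls(df["term"].astype(str).tolist(), df["count"].to_numpy())


def tokenize(text: str) -> list[str]:
    """Lowercase and split on the package's token rule."""
    return _TOKEN_RE.findall(text.lower())


def load_corpus(text_path: str | Path, metadata_path: str | Path | None = None) -> list[Document]:
    """Read one document per line, optionally joining metadata by ``doc_id``.

    Documents are assigned sequential ids ``d0, d1, ...`` matching what
    :func:`save_corpus` and the simulator write.  If a metadata table is given
    its ``doc_id`` column must cover exactly the same ids.
    """
    text_path = Path(text_path)
    if not text_path.exists():
        raise FileNotFoundError(str(text_path))
    docs: list[Document] = []
    with open(text_path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            docs.append(Document(doc_id=f"d{i}", tokens=tokenize(line)))
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=None, engine="python", dtype={"doc_id": str})
        if "doc_id" not in meta.columns:
            raise ValueError("metadata table must have a doc_id column")
        meta_ids = set(meta["doc_id"])
        doc_ids = {d.doc_id for d in docs}
        missing = sorted(doc_ids - meta_ids)
        extra = sorted(meta_ids - doc_ids)
        if missing or extra:
            raise ValueError(
                f"doc_id mismatch between text and metadata: "
                f"missing from metadata {missing[:10]}, unknown in metadata {extra[:10]}"
            )
        by_id = meta.set_index("doc_id")
        for d in docs:
            d.metadata = by_id.loc[d.doc_id].to_dict()
    return docs


def save_corpus(docs: list[Document], text_path: str | Path) -> None:
    """Write documents one per line (space-joined tokens)."""
    with open(text_path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(" ".join(d.tokens) + "\n")


def _phrase_pass(docs: list[Document], delta: float, threshold: float) -> tuple[list[Document], int]:
    """One merging pass; returns new docs and the number of distinct merged pairs."""
    uni: Counter = Counter()
    bi: Counter = Counter()
    for d in docs:
        uni.update(d.tokens)
        for a, b in zip(d.tokens, d.tokens[1:]):
            bi[(a, b)] += 1
    v = len(uni)
    qualifying = set()
    for (a, b), c_ab in bi.items():
        score = (c_ab - delta) / (uni[a] * uni[b])
        if score * v > threshold:
            qualifying.add((a, b))
    if not qualifying:
        return docs, 0
    out = []
    for d in docs:
        toks, i = [], 0
        while i < len(d.tokens):
            if i + 1 < len(d.tokens) and (d.tokens[i], d.tokens[i + 1]) in qualifying:
                toks.append(d.tokens[i] + "_" + d.tokens[i + 1])
                i += 2
            else:
                toks.append(d.tokens[i])
                i += 1
        out.append(Document(d.doc_id, toks, d.metadata))
    return out, len(qualifying)


def merge_phrases(
    docs: list[Document], delta: float = 5.0, threshold: float = 10.0, passes: int = 2
) -> list[Document]:
    """Merge frequent adjacent pairs into single underscore-joined terms.

    A pair ``(a, b)`` qualifies when ``(count(ab) - delta) / (count(a) * count(b))``
    times the current vocabulary size exceeds ``threshold``.  Counts are
    re-estimated each pass, so repeated passes build multiword terms.  Merging
    is greedy left-to-right and non-overlapping within a document.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    for _ in range(passes):
        docs, n_merged = _phrase_pass(docs, delta, threshold)
        if n_merged == 0:
            break
    return docs


def build_vocabulary(docs: list[Document], min_count: int = 5) -> Vocabulary:
    """Count terms across documents, dropping those seen fewer than ``min_count`` times.

    Probabilities are renormalized over the retained terms; term order is by
    descending count, ties by first appearance, so vocabulary indices are
    deterministic.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter = Counter()
    first_seen: dict[str, int] = {}
    pos = 0
    for d in docs:
        for t in d.tokens:
            counts[t] += 1
            if t not in first_seen:
                first_seen[t] = pos
                pos += 1
    kept = [(t, c) for t, c in counts.items() if c >= min_count]
    if not kept:
        raise ValueError(f"no terms reach min_count={min_count}: vocabulary is empty")
    kept.sort(key=lambda tc: (-tc[1], first_seen[tc[0]]))
    return Vocabulary([t for t, _ in kept], np.array([c for _, c in kept]))
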