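"""Latent semantic dimensions (e.g., a gender axis) and topic loadings.

An axis is built from anchor word pairs (pole_a term, pole_b term), as the
normalized mean of the normalized per-pair difference vectors
v(pole_b) − v(pole_a).  The loading of a topic is the cosine between its atom
vector and the axis; by convention positive loadings point toward pole_b
(for the shipped gender pairs: the feminine pole).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atoms import AtomDictionary
from .embedding import Embedding, cosine, nearest_words

__all__ = ["GENDER_PAIRS", "SemanticDimension", "build_dimension", "topic_loading", "rank_topics"]

#: Default anchor pairs for a gender axis (pole_a = masculine, pole_b = feminine).
GENDER_PAIRS: list[tuple[str, str]] = [
    ("he", "she"),
    ("man", "woman"),
    ("him", "her"),
    ("male", "female"),
    ("father", "mother"),
    ("son", "daughter"),
    ("husband", "wife"),
    ("brother", "sister"),
]


@dataclass
class SemanticDimension:
    name: str
    pairs: list[tuple[str, str]]  # the pairs actually used (in-vocabulary)
    axis: np.ndarray  # unit vector pointing from pole_a toward pole_b
    skipped: list[tuple[str, str]]  # pairs dropped for missing anchors


def build_dimension(
    pairs: list[tuple[str, str]], emb: Embedding, name: str = "dimension"
) -> SemanticDimension:
    """Mean-of-normalized-differences axis from anchor pairs.

    Pairs with an out-of-vocabulary anchor are skipped (and reported on the
    returned object); at least one pair must survive.
    """
    used, skipped, diffs = [], [], []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"identical pole words in pair ({a!r}, {b!r})")
        if a not in emb.vocab or b not in emb.vocab:
            skipped.append((a, b))
            continue
        d = emb.vector(b) - emb.vector(a)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError(f"anchor pair ({a!r}, {b!r}) has identical vectors")
        diffs.append(d / n)
        used.append((a, b))
    if not diffs:
        raise ValueError(f"no usable anchor pairs (skipped: {skipped})")
    axis = np.mean(diffs, axis=0)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("anchor differences cancel; axis undefined")
    return SemanticDimension(name=name, pairs=used, axis=axis / n, skipped=skipped)


def topic_loading(atom: np.ndarray, dim: SemanticDimension) -> float:
    """Cosine between an atom vector and the axis (positive = pole_b side)."""
    return cosine(atom, dim.axis)


def rank_topics(
    dct: AtomDictionary, dim: SemanticDimension, emb: Embedding, top_n: int = 7
) -> pd.DataFrame:
    """All topics sorted by loading (descending: pole_b extreme first), each
    labeled with its nearest terms for qualitative audit."""
    rows = []
    for k in range(dct.K):
        rows.append(
            {
                "topic_id": k,
                "loading": topic_loading(dct.atoms[k], dim),
                "top_terms": " ".join(t for t, _ in nearest_words(dct.atoms[k], emb, top_n)),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["loading", "topic_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
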