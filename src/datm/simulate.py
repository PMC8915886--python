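"""Synthetic corpora drawn from the latent-variable generative model.

Ground truth for every pipeline stage: a planted semantic space (near-
orthogonal unit atoms, word vectors that are sparse combinations of atoms
plus noise, Zipfian unigram frequencies, a fixed global vector c0, and a
binary semantic axis), and documents emitted token by token from the mixture

    Pr[w at t | ct] = α·p(w) + (1−α)·exp(γ·⟨c̃t, w⟩) / Z,   c̃t = β·c0 + (1−β)·ct,

where the gist ct makes a slow mean-reverting random walk around the
document's dominant atom and γ (``gist_strength``) sets the emission scale
— with unit-norm planted vectors the inner products alone would make the
exponential term nearly uniform over the vocabulary.  Each atom carries a pole (±1) along the planted
axis; a document-level group label tilts the choice of dominant atom toward
its pole, emulating how gendered topics co-vary with victim sex in real
narratives.  The partition function Z is computed exactly over the synthetic
vocabulary.  Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .corpus import Document
from .embedding import Embedding
from .gist import NO_TOPIC

__all__ = [
    "SimConfig",
    "SimSpace",
    "SimCorpus",
    "plant_space",
    "generate_corpus",
    "window_truth",
    "empirical_atoms",
    "evaluate_recovery",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults are the package's standard test scale: a vocabulary of 2,000
    terms in a 50-dimensional space with 20 planted topics, 2,000 documents
    of 100 tokens — minutes of work on one CPU — in the strong-separation
    regime (each word loads on a single atom, low emission smoothing).
    """

    V: int = 2000
    N: int = 50
    K_true: int = 20
    s_true: int = 1
    alpha: float = 0.1  # weight of the frequency term in the emission mixture
    beta: float = 0.2  # weight of the global vector in the combined context
    drift: float = 0.05  # per-step gist drift rate
    gist_strength: float = 6.0  # emission scale: exp(gist_strength * <c, w>)
    docs: int = 2000
    doc_len: int = 100
    axis_gap: float = 0.4  # atom offset along the planted axis
    group_effect: float = 1.2  # log-scale tilt of dominant-atom choice by group
    noise_sd: float = 0.0  # per-coordinate Gaussian noise on word vectors
    zipf_exponent: float = 1.0
    n_anchor_pairs: int = 8
    anchor_gap: float = 0.8  # axis component of anchor-word vectors
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if not 0 <= self.beta < 1:
            raise ValueError("beta must be in [0, 1)")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.gist_strength <= 0:
            raise ValueError("gist_strength must be positive")
        if min(self.V, self.N, self.K_true, self.docs, self.doc_len, self.s_true) < 1:
            raise ValueError("all sizes must be positive")
        if self.K_true >= self.V:
            raise ValueError("need K_true < V")
        if self.N < self.K_true + 2:
            raise ValueError("need N >= K_true + 2 (atoms plus axis plus c0)")
        if self.s_true > self.K_true:
            raise ValueError("s_true cannot exceed K_true")


@dataclass
class SimSpace:
    """Planted ground truth: atoms, word vectors, frequencies, c0 and axis."""

    atoms: np.ndarray  # K_true x N, unit rows
    words: np.ndarray  # V x N
    terms: list[str]
    p: np.ndarray  # Zipfian unigram probabilities
    c0: np.ndarray
    axis: np.ndarray
    pole: np.ndarray  # per-atom pole in {-1, +1}
    word_atom: np.ndarray  # dominant atom per word (-1 for anchor words)
    anchor_pairs: list[tuple[str, str]]
    true_codes: np.ndarray  # V x K_true planted coefficients (zero rows for anchors)


def plant_space(cfg: SimConfig) -> SimSpace:
    """Construct the planted semantic space (seeded by ``cfg.seed``).

    K_true + 2 orthonormal directions are drawn by QR of a Gaussian matrix:
    the first K_true give the atom subspace, the last two give the axis and
    c0.  Atom k is the unit vector along q_k + pole_k·axis_gap·axis with
    alternating poles.  Regular word w loads on dominant atom (w mod K_true)
    with coefficient 1 plus, when s_true > 1, up to s_true−1 extra atoms with
    Gaussian coefficients, plus optional Gaussian noise.  Anchor pairs sit at
    ±anchor_gap along the axis (plus a shared random base), giving the
    dimension builder in-vocabulary poles.
    """
    rng = np.random.default_rng(cfg.seed)
    K, N, V = cfg.K_true, cfg.N, cfg.V
    q, _ = np.linalg.qr(rng.standard_normal((N, K + 2)))
    base, axis, c0 = q[:, :K].T, q[:, K], q[:, K + 1]
    pole = np.where(np.arange(K) % 2 == 0, -1, 1)
    atoms = base + cfg.axis_gap * pole[:, None] * axis
    atoms /= np.linalg.norm(atoms, axis=1, keepdims=True)

    n_anchor = 2 * cfg.n_anchor_pairs
    v_reg = V - n_anchor
    if v_reg < K:
        raise ValueError("vocabulary too small for the planted atoms and anchors")
    word_atom = np.concatenate([np.arange(v_reg) % K, np.full(n_anchor, -1)])
    codes = np.zeros((V, K))
    codes[np.arange(v_reg), word_atom[:v_reg]] = 1.0
    if cfg.s_true > 1:
        for w in range(v_reg):
            others = rng.choice(np.delete(np.arange(K), word_atom[w]), size=cfg.s_true - 1, replace=False)
            codes[w, others] = rng.normal(0.0, 0.4, size=cfg.s_true - 1)
    words = codes @ atoms
    if cfg.noise_sd > 0:
        words = words + rng.normal(0.0, cfg.noise_sd, size=(V, N))

    terms = [f"w{i}" for i in range(v_reg)]
    anchor_pairs = []
    for j in range(cfg.n_anchor_pairs):
        u = 0.3 * rng.standard_normal(N)
        u -= (u @ axis) * axis  # keep the base off-axis so pairs differ only by pole
        a_vec = u - cfg.anchor_gap * axis
        b_vec = u + cfg.anchor_gap * axis
        words[v_reg + 2 * j] = a_vec / np.linalg.norm(a_vec)
        words[v_reg + 2 * j + 1] = b_vec / np.linalg.norm(b_vec)
        terms += [f"fa{j}", f"fb{j}"]
        anchor_pairs.append((f"fa{j}", f"fb{j}"))

    ranks = rng.permutation(V) + 1
    p = 1.0 / ranks.astype(np.float64) ** cfg.zipf_exponent
    p /= p.sum()
    return SimSpace(
        atoms=atoms, words=words, terms=terms, p=p, c0=c0, axis=axis, pole=pole,
        word_atom=word_atom, anchor_pairs=anchor_pairs, true_codes=codes,
    )


@dataclass
class SimCorpus:
    """Generated documents plus per-token ground-truth topics."""

    docs: list[Document]
    token_topics: list[np.ndarray]  # nearest planted atom to ct, per token
    space: SimSpace
    config: SimConfig

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "doc_id": d.doc_id,
                    "group": d.metadata["group"],
                    "true_dominant_topic": d.metadata["true_dominant_topic"],
                    "word_count": d.metadata["word_count"],
                }
                for d in self.docs
            ]
        )

    def save(self, text_path: str | Path, metadata_path: str | Path) -> None:
        with open(text_path, "w", encoding="utf-8") as fh:
            for d in self.docs:
                fh.write(" ".join(d.tokens) + "\n")
        self.metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def generate_corpus(cfg: SimConfig, space: SimSpace) -> SimCorpus:
    """Emit documents token by token from the mixture model.

    Per document: a group label (a/b, balanced) tilts the dominant-atom
    probabilities by exp(±group_effect·pole/2); the gist starts at the
    dominant atom and follows ct+1 ∝ (1−drift)·ct + drift·(atom + η) with
    Gaussian η projected off c0 (the model keeps c0 ⊥ ct); tokens are drawn
    from α·p + (1−α)·softmax(gist_strength·W·c̃t) with the partition
    function computed exactly over the vocabulary.
    """
    rng = np.random.default_rng([cfg.seed, 2**16 + 1])
    K, V, T = cfg.K_true, cfg.V, cfg.doc_len
    W = space.words
    docs: list[Document] = []
    token_topics: list[np.ndarray] = []
    groups = rng.integers(0, 2, size=cfg.docs)  # 0 = group a, 1 = group b
    for i in range(cfg.docs):
        sign = 1.0 if groups[i] else -1.0
        wk = np.exp(0.5 * cfg.group_effect * sign * space.pole)
        k = int(rng.choice(K, p=wk / wk.sum()))
        atom = space.atoms[k]
        gists = np.empty((T, cfg.N))
        ct = atom.copy()
        for t in range(T):
            gists[t] = ct
            eta = rng.standard_normal(cfg.N)
            eta -= (eta @ space.c0) * space.c0
            eta /= np.linalg.norm(eta)
            nxt = (1 - cfg.drift) * ct + cfg.drift * (atom + eta)
            ct = nxt / np.linalg.norm(nxt)
        c_tilde = cfg.beta * space.c0 + (1 - cfg.beta) * gists
        scores = cfg.gist_strength * (c_tilde @ W.T)
        scores -= scores.max(axis=1, keepdims=True)
        ez = np.exp(scores)
        probs = cfg.alpha * space.p + (1 - cfg.alpha) * ez / ez.sum(axis=1, keepdims=True)
        cdf = np.cumsum(probs, axis=1)
        u = rng.random(T) * cdf[:, -1]
        ids = (cdf >= u[:, None]).argmax(axis=1)
        truth = (gists @ space.atoms.T).argmax(axis=1)
        docs.append(
            Document(
                doc_id=f"d{i}",
                tokens=[space.terms[j] for j in ids],
                metadata={
                    "group": "b" if groups[i] else "a",
                    "true_dominant_topic": k,
                    "word_count": T,
                },
            )
        )
        token_topics.append(truth.astype(np.int64))
    return SimCorpus(docs=docs, token_topics=token_topics, space=space, config=cfg)


def window_truth(token_topics: np.ndarray, bounds: list[tuple[int, int]]) -> np.ndarray:
    """Majority-vote planted topic for each (start, end) token window
    (ties broken by the lowest topic id)."""
    out = np.empty(len(bounds), dtype=np.int64)
    for i, (a, b) in enumerate(bounds):
        ids, counts = np.unique(token_topics[a:b], return_counts=True)
        out[i] = ids[np.argmax(counts)]
    return out


def empirical_atoms(emb: Embedding, space: SimSpace) -> np.ndarray:
    """Planted-topic stand-ins in a *trained* embedding space: the normalized
    mean of the unit vectors of each topic's words that survived into the
    trained vocabulary.  Lets atom-recovery metrics compare a dictionary
    fitted in trained space against ground truth that lives in the planted
    space."""
    unit = emb.unit_vectors()
    K = space.atoms.shape[0]
    out = np.zeros((K, emb.dim))
    for k in range(K):
        terms = [t for t, a in zip(space.terms, space.word_atom) if a == k and t in emb.vocab]
        if not terms:
            raise ValueError(f"planted topic {k} has no words in the trained vocabulary")
        m = unit[[emb.vocab.index[t] for t in terms]].mean(axis=0)
        out[k] = m / np.linalg.norm(m)
    return out


def evaluate_recovery(
    fitted_atoms: np.ndarray,
    true_atoms: np.ndarray,
    assigned: np.ndarray | None = None,
    true_labels: np.ndarray | None = None,
) -> dict:
    """Match fitted atoms to planted atoms and score the recovery.

    The one-to-one matching maximizes total |cosine| (Hungarian assignment).
    Returns the matching (fitted index → true index), per-pair |cosine|, the
    mean |cosine| over matched pairs, and — when window-level ``assigned``
    fitted-atom ids and ``true_labels`` planted ids are supplied — the
    fraction of windows whose fitted atom maps to the planted topic
    (unassigned sentinel windows count as errors).
    """
    F = np.asarray(fitted_atoms, dtype=np.float64)
    Tm = np.asarray(true_atoms, dtype=np.float64)
    if F.size == 0 or Tm.size == 0:
        raise ValueError("empty atom matrices")
    Fn = F / np.linalg.norm(F, axis=1, keepdims=True)
    Tn = Tm / np.linalg.norm(Tm, axis=1, keepdims=True)
    C = np.abs(Fn @ Tn.T)
    ri, ci = linear_sum_assignment(-C)
    matching = {int(i): int(j) for i, j in zip(ri, ci)}
    pair_cos = C[ri, ci]
    result = {
        "matching": matching,
        "pair_abs_cosine": pair_cos,
        "mean_abs_cosine": float(pair_cos.mean()),
    }
    if assigned is not None and true_labels is not None:
        assigned = np.asarray(assigned)
        true_labels = np.asarray(true_labels)
        if assigned.shape != true_labels.shape:
            raise ValueError("assigned and true_labels must align")
        mapped = np.array(
            [matching.get(int(a), NO_TOPIC - 1) if a != NO_TOPIC else NO_TOPIC - 1 for a in assigned]
        )
        result["window_accuracy"] = float(np.mean(mapped == true_labels))
    return result
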