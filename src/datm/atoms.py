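"""Discourse atoms: sparse dictionary learning over word vectors.

A dictionary of K unit-norm atom vectors is fit so that every (unit-normalized)
word vector is approximately a sparse linear combination of at most ``s``
atoms.  Atoms are interpreted as topics through their nearest words.  The
sparse-coding stage is orthogonal matching pursuit (OMP) with a least-squares
refit after each greedy selection; the dictionary update is the classic
per-atom rank-1 SVD of the restricted residual.  Candidate K values are
scored by topic coherence, inter-atom distinctness, and reconstruction R².
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import Embedding, nearest_words

__all__ = [
    "AtomDictionary",
    "ModelScore",
    "omp_code",
    "ksvd_fit",
    "reconstruction_r2",
    "score_model",
    "choose_from_scores",
    "select_k",
    "topics_table",
]

_ATOM_NORM_TOL = 1e-8


@dataclass
class AtomDictionary:
    """K x N unit-norm atoms plus the V x K sparse codes of the word vectors."""

    atoms: np.ndarray
    codes: np.ndarray
    s: int

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        self.codes = np.asarray(self.codes, dtype=np.float64)
        if self.atoms.ndim != 2 or self.atoms.shape[0] < 1:
            raise ValueError("need a K x N atom matrix with K >= 1")
        if self.codes.shape[1] != self.atoms.shape[0]:
            raise ValueError("codes must be V x K")
        norms = np.linalg.norm(self.atoms, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("atom rows must be unit-norm")
        if np.any((self.codes != 0).sum(axis=1) > self.s):
            raise ValueError(f"a code row exceeds sparsity s={self.s}")

    @property
    def K(self) -> int:
        return self.atoms.shape[0]

    @property
    def dim(self) -> int:
        return self.atoms.shape[1]

    def save(self, atoms_path: str | Path, codes_path: str | Path) -> None:
        with open(atoms_path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.K} {self.dim} {self.s}\n")
            for k in range(self.K):
                fh.write(f"atom{k} " + " ".join(f"{x:.17g}" for x in self.atoms[k]) + "\n")
        rows, cols = np.nonzero(self.codes)
        pd.DataFrame(
            {"word_index": rows, "atom_index": cols, "coefficient": self.codes[rows, cols]}
        ).to_csv(codes_path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def load(cls, atoms_path: str | Path, codes_path: str | Path, n_words: int) -> "AtomDictionary":
        with open(atoms_path, encoding="utf-8") as fh:
            k, n, s = (int(x) for x in fh.readline().split())
            atoms = np.array(
                [[float(x) for x in fh.readline().split()[1 : n + 1]] for _ in range(k)]
            )
        codes = np.zeros((n_words, k))
        trip = pd.read_csv(codes_path, sep="\t")
        codes[trip["word_index"], trip["atom_index"]] = trip["coefficient"]
        return cls(atoms, codes, s)


@dataclass
class ModelScore:
    """Quality metrics for one fitted dictionary size K."""

    K: int
    coherence: float  # mean over atoms of mean pairwise cosine among top-n words
    distinctness: float  # 1 - mean pairwise |cosine| among atom vectors
    r2: float  # 1 - ||X - codes @ atoms||_F^2 / ||X||_F^2


def omp_code(x: np.ndarray, atoms: np.ndarray, s: int) -> np.ndarray:
    """Greedy sparse code of ``x`` over unit-norm ``atoms`` with <= s nonzeros.

    At each step the atom with the largest |inner product| with the current
    residual is added and the coefficients of all selected atoms are refit by
    least squares, so the residual stays orthogonal to the selected span.
    Stops early when the residual is numerically zero.
    """
    x = np.asarray(x, dtype=np.float64)
    atoms = np.asarray(atoms, dtype=np.float64)
    K = atoms.shape[0]
    if not 1 <= s <= min(K, atoms.shape[1]):
        raise ValueError(f"sparsity s={s} out of range for K={K}, N={atoms.shape[1]}")
    code = np.zeros(K)
    support: list[int] = []
    residual = x.copy()
    for _ in range(s):
        if np.linalg.norm(residual) <= 1e-12:
            break
        corr = np.abs(atoms @ residual)
        corr[support] = -np.inf
        j = int(np.argmax(corr))
        support.append(j)
        sub = atoms[support]  # |S| x N
        coef, *_ = np.linalg.lstsq(sub.T, x, rcond=None)
        residual = x - sub.T @ coef
    if support:
        code[support] = coef
    return code


def _code_all(X: np.ndarray, atoms: np.ndarray, s: int) -> np.ndarray:
    return np.stack([omp_code(row, atoms, s) for row in X])


def _init_atoms(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Seed the dictionary from K distinct data rows (unit-normalized)."""
    norms = np.linalg.norm(X, axis=1)
    candidates = np.flatnonzero(norms > 1e-12)
    pick = rng.choice(candidates, size=K, replace=False)
    atoms = X[pick] / norms[pick, None]
    return atoms


def _fix_signs(dct: AtomDictionary) -> None:
    """Flip each atom so its largest-|coefficient| user has a positive loading."""
    for k in range(dct.K):
        users = np.flatnonzero(dct.codes[:, k])
        if len(users) == 0:
            continue
        top = users[np.argmax(np.abs(dct.codes[users, k]))]
        if dct.codes[top, k] < 0:
            dct.atoms[k] = -dct.atoms[k]
            dct.codes[:, k] = -dct.codes[:, k]


def ksvd_fit(
    X: np.ndarray,
    K: int,
    s: int = 5,
    iters: int = 30,
    seed: int = 0,
    return_history: bool = False,
):
    """Fit K unit-norm atoms to the rows of X by K-SVD.

    Alternates OMP sparse coding of every row with per-atom dictionary
    updates: for atom k, the residual of the rows currently using it (with
    atom k's own contribution added back) is reduced by its leading singular
    pair, which simultaneously re-estimates the atom direction and those
    rows' coefficients.  Atoms used by no row are re-seeded from the
    worst-reconstructed row.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=np.float64)
    V, N = X.shape
    if K >= V:
        raise ValueError("need more samples than atoms (K < V)")
    if K < 1:
        raise ValueError("K must be >= 1")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    atoms = _init_atoms(X, K, rng)
    codes = np.zeros((V, K))
    history = []
    n_reseeded = 0
    for _ in range(iters):
        codes = _code_all(X, atoms, s)
        for k in range(K):
            users = np.flatnonzero(codes[:, k])
            if len(users) == 0:
                err = np.linalg.norm(X - codes @ atoms, axis=1)
                worst = int(np.argmax(err))
                atoms[k] = X[worst] / np.linalg.norm(X[worst])
                n_reseeded += 1
                continue
            # residual without atom k's contribution, restricted to its users
            E = X[users] - codes[users] @ atoms + np.outer(codes[users, k], atoms[k])
            u, sv, vt = np.linalg.svd(E, full_matrices=False)
            atoms[k] = vt[0]
            codes[users, k] = sv[0] * u[:, 0]
        history.append(float(np.linalg.norm(X - codes @ atoms) ** 2))
    codes = _code_all(X, atoms, s)
    dct = AtomDictionary(atoms=atoms, codes=codes, s=s)
    _fix_signs(dct)
    dct.n_reseeded = n_reseeded  # diagnostic, not part of the frozen contract
    if return_history:
        return dct, history
    return dct


def reconstruction_r2(X: np.ndarray, dct: AtomDictionary) -> float:
    """Fraction of the (uncentered) squared norm of X explained by codes @ atoms."""
    X = np.asarray(X, dtype=np.float64)
    total = float(np.linalg.norm(X) ** 2)
    if total == 0:
        raise ValueError("R^2 undefined for an all-zero matrix")
    resid = float(np.linalg.norm(X - dct.codes @ dct.atoms) ** 2)
    return 1.0 - resid / total


def _coherence(dct: AtomDictionary, emb: Embedding, top_n: int) -> float:
    """Mean over atoms of the mean pairwise cosine among each atom's top words."""
    unit = emb.unit_vectors()
    per_atom = []
    for k in range(dct.K):
        terms = [t for t, _ in nearest_words(dct.atoms[k], emb, top_n)]
        idx = [emb.vocab.index[t] for t in terms]
        G = unit[idx] @ unit[idx].T
        iu = np.triu_indices(len(idx), k=1)
        per_atom.append(float(G[iu].mean()))
    return float(np.mean(per_atom))


def _distinctness(dct: AtomDictionary) -> float:
    G = dct.atoms @ dct.atoms.T
    iu = np.triu_indices(dct.K, k=1)
    return 1.0 - float(np.abs(G[iu]).mean())


def score_model(dct: AtomDictionary, emb: Embedding, top_n: int = 10) -> ModelScore:
    """Coherence / distinctness / R² for one fitted dictionary."""
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    if top_n > len(emb.vocab):
        raise ValueError("top_n exceeds vocabulary size")
    return ModelScore(
        K=dct.K,
        coherence=_coherence(dct, emb, top_n),
        distinctness=_distinctness(dct),
        r2=reconstruction_r2(emb.unit_vectors(), dct),
    )


def choose_from_scores(table: pd.DataFrame) -> int:
    """Selection rule for :func:`select_k`: min-max normalize each metric
    across the grid (a constant metric counts 0.5 everywhere), take the K
    with the highest mean normalized score, break ties toward the smallest K.
    """
    norm = pd.DataFrame(index=table.index)
    for col in ("coherence", "distinctness", "r2"):
        lo, hi = table[col].min(), table[col].max()
        norm[col] = 0.5 if hi - lo < 1e-15 else (table[col] - lo) / (hi - lo)
    combined = norm.mean(axis=1)
    ordered = table.assign(combined=combined).sort_values(["K"])
    return int(ordered.loc[ordered["combined"].idxmax(), "K"])


def select_k(
    X: np.ndarray,
    emb: Embedding,
    k_grid: list[int],
    s: int = 5,
    iters: int = 30,
    seed: int = 0,
    top_n: int = 10,
) -> tuple[pd.DataFrame, int, dict[int, AtomDictionary]]:
    """Fit every K in the grid and choose the K balancing all three metrics.

    Each metric is min-max normalized across the grid (constant metrics count
    0.5 everywhere) and the K with the highest mean normalized score wins;
    ties go to the smallest K.  The full score table is returned so callers
    can apply their own rule.
    """
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    if any(k >= X.shape[0] for k in k_grid):
        raise ValueError("every K must be < number of word vectors")
    fits: dict[int, AtomDictionary] = {}
    scores = []
    for k in sorted(k_grid):
        dct = ksvd_fit(X, K=k, s=s, iters=iters, seed=seed)
        fits[k] = dct
        sc = score_model(dct, emb, top_n=top_n)
        scores.append({"K": k, "coherence": sc.coherence, "distinctness": sc.distinctness, "r2": sc.r2})
    table = pd.DataFrame(scores)
    best = choose_from_scores(table)
    norm = pd.DataFrame(index=table.index)
    for col in ("coherence", "distinctness", "r2"):
        lo, hi = table[col].min(), table[col].max()
        norm[col] = 0.5 if hi - lo < 1e-15 else (table[col] - lo) / (hi - lo)
    table["combined"] = norm.mean(axis=1)
    return table, best, fits


def topics_table(dct: AtomDictionary, emb: Embedding, top_n: int = 25) -> pd.DataFrame:
    """Ranked nearest words per topic (topic_id, rank, term, cosine)."""
    rows = []
    for k in range(dct.K):
        for rank, (term, cos) in enumerate(nearest_words(dct.atoms[k], emb, top_n), start=1):
            rows.append({"topic_id": k, "rank": rank, "term": term, "cosine": cos})
    return pd.DataFrame(rows)
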