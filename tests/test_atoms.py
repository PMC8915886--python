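from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from datm import (
    AtomDictionary,
    Embedding,
    SimConfig,
    Vocabulary,
    choose_from_scores,
    ksvd_fit,
    omp_code,
    plant_space,
    reconstruction_r2,
    score_model,
    select_k,
    evaluate_recovery,
)
from datm.atoms import _code_all


def random_unit_atoms(rng, K, N):
    A = rng.standard_normal((K, N))
    return A / np.linalg.norm(A, axis=1, keepdims=True)


def exhaustive_best_residual(x, atoms, s):
    best = np.inf
    for sup in combinations(range(len(atoms)), s):
        sub = atoms[list(sup)]
        coef, *_ = np.linalg.lstsq(sub.T, x, rcond=None)
        best = min(best, np.linalg.norm(x - sub.T @ coef))
    return best


class TestOMP:
    def test_exact_atom_gives_indicator(self):
        rng = np.random.default_rng(0)
        A = random_unit_atoms(rng, 6, 8)
        code = omp_code(A[3], A, s=4)
        want = np.zeros(6)
        want[3] = 1.0
        assert np.allclose(code, want, atol=1e-10)

    def test_full_support_reconstructs_exactly(self):
        rng = np.random.default_rng(1)
        A = random_unit_atoms(rng, 4, 6)  # full row rank, N >= K
        x = rng.standard_normal(6)
        code = omp_code(x, A, s=4)
        # residual is the projection error onto the atom span
        proj, *_ = np.linalg.lstsq(A.T, x, rcond=None)
        assert np.linalg.norm(A.T @ code - A.T @ proj) <= 1e-8

    def test_sparsity_out_of_range(self):
        rng = np.random.default_rng(2)
        A = random_unit_atoms(rng, 4, 6)
        for s in (0, 5):
            with pytest.raises(ValueError):
                omp_code(np.ones(6), A, s=s)

    def test_residual_orthogonal_to_selected_atoms(self):
        rng = np.random.default_rng(3)
        A = random_unit_atoms(rng, 8, 10)
        x = rng.standard_normal(10)
        code = omp_code(x, A, s=3)
        resid = x - A.T @ code
        for j in np.flatnonzero(code):
            assert abs(A[j] @ resid) <= 1e-10

    def test_equals_exhaustive_search_on_orthonormal_dictionaries(self):
        # For an orthonormal dictionary greedy selection with refit is exactly
        # the best s-subset, for any input vector.
        rng = np.random.default_rng(4)
        for _ in range(25):
            K = int(rng.integers(4, 9))
            N = K + int(rng.integers(0, 4))
            A = np.linalg.qr(rng.standard_normal((N, K)))[0].T
            x = rng.standard_normal(N)
            s = int(rng.integers(1, 4))
            r = np.linalg.norm(x - A.T @ omp_code(x, A, s))
            assert r - exhaustive_best_residual(x, A, s) <= 1e-9

    def test_recovers_planted_support_on_incoherent_dictionary(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            Q = np.linalg.qr(rng.standard_normal((50, 8)))[0].T
            A = Q + 0.1 * rng.standard_normal((8, 50))
            A /= np.linalg.norm(A, axis=1, keepdims=True)
            s = int(rng.integers(1, 4))
            sup = rng.choice(8, s, replace=False)
            coef = rng.uniform(0.5, 1.5, s) * rng.choice([-1, 1], s)
            x = A[sup].T @ coef
            code = omp_code(x, A, s)
            assert set(np.flatnonzero(code)) == set(sup)
            assert np.linalg.norm(x - A.T @ code) <= 1e-9

    def test_agrees_with_sklearn_omp(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(6)
        Q = np.linalg.qr(rng.standard_normal((30, 6)))[0].T
        A = Q + 0.05 * rng.standard_normal((6, 30))
        A /= np.linalg.norm(A, axis=1, keepdims=True)
        sup = [1, 4]
        x = A[sup].T @ np.array([1.0, -0.8])
        ours = omp_code(x, A, s=2)
        ref = sklearn.OrthogonalMatchingPursuit(
            n_nonzero_coefs=2, fit_intercept=False
        ).fit(A.T, x)
        assert np.allclose(ours, ref.coef_, atol=1e-8)


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(V=300, N=30, K_true=10, s_true=3, noise_sd=0.0,
                    n_anchor_pairs=2, seed=11)
    space = plant_space(cfg)
    X = space.words / np.linalg.norm(space.words, axis=1, keepdims=True)
    return space, X


class TestKSVD:
    def test_recovers_planted_dictionary(self, planted):
        space, X = planted
        dct = ksvd_fit(X, K=10, s=3, iters=25, seed=11)
        rep = evaluate_recovery(dct.atoms, space.atoms)
        assert rep["mean_abs_cosine"] >= 0.95

    def test_atoms_unit_norm_and_codes_sparse(self, planted):
        _, X = planted
        dct = ksvd_fit(X, K=10, s=3, iters=5, seed=0)
        assert np.allclose(np.linalg.norm(dct.atoms, axis=1), 1.0, atol=1e-8)
        assert ((dct.codes != 0).sum(axis=1) <= 3).all()

    def test_objective_non_increasing(self, planted):
        _, X = planted
        _, history = ksvd_fit(X, K=10, s=3, iters=10, seed=3, return_history=True)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_k1_matches_leading_singular_vector(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 6)) @ np.diag([5, 2, 1, 0.5, 0.2, 0.1])
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        dct = ksvd_fit(Xn, K=1, s=1, iters=10, seed=8)
        v1 = np.linalg.svd(Xn, full_matrices=False)[2][0]
        assert abs(dct.atoms[0] @ v1) >= 0.999

    @pytest.mark.parametrize("kwargs", [{"K": 400}, {"K": 5, "iters": 0}])
    def test_preconditions(self, planted, kwargs):
        _, X = planted
        with pytest.raises(ValueError):
            ksvd_fit(X, s=2, seed=0, **{"iters": 5, **kwargs})

    def test_serialization_roundtrip(self, planted, tmp_path):
        _, X = planted
        dct = ksvd_fit(X, K=6, s=2, iters=3, seed=1)
        dct.save(tmp_path / "atoms.txt", tmp_path / "codes.tsv")
        back = AtomDictionary.load(tmp_path / "atoms.txt", tmp_path / "codes.tsv", X.shape[0])
        assert np.max(np.abs(back.atoms - dct.atoms)) <= 1e-8
        assert np.max(np.abs(back.codes - dct.codes)) <= 1e-8


class TestMetrics:
    def test_perfect_reconstruction_r2_is_one(self):
        rng = np.random.default_rng(9)
        A = random_unit_atoms(rng, 3, 5)
        codes = rng.standard_normal((20, 3))
        X = codes @ A
        assert reconstruction_r2(X, AtomDictionary(A, codes, 3)) == pytest.approx(1.0)

    def test_zero_codes_r2_is_zero(self):
        rng = np.random.default_rng(10)
        A = random_unit_atoms(rng, 3, 5)
        X = rng.standard_normal((20, 5))
        assert reconstruction_r2(X, AtomDictionary(A, np.zeros((20, 3)), 3)) == pytest.approx(0.0)

    def test_r2_undefined_for_zero_matrix(self):
        rng = np.random.default_rng(11)
        A = random_unit_atoms(rng, 3, 5)
        with pytest.raises(ValueError):
            reconstruction_r2(np.zeros((4, 5)), AtomDictionary(A, np.zeros((4, 3)), 3))

    def test_r2_monotone_in_sparsity_for_fixed_atoms(self):
        rng = np.random.default_rng(12)
        A = random_unit_atoms(rng, 8, 12)
        X = rng.standard_normal((60, 12))
        r2s = []
        for s in (1, 2, 4):
            codes = _code_all(X, A, s)
            r2s.append(reconstruction_r2(X, AtomDictionary(A, codes, s)))
        assert r2s[0] <= r2s[1] <= r2s[2]

    def test_orthonormal_atoms_have_distinctness_one(self):
        vocab = Vocabulary([f"x{i}" for i in range(6)], np.ones(6, dtype=np.int64))
        emb = Embedding(vocab, np.eye(6))
        atoms = np.eye(6)[:3]
        codes = np.zeros((6, 3))
        codes[:3, :3] = np.eye(3)
        sc = score_model(AtomDictionary(atoms, codes, 1), emb, top_n=2)
        assert sc.distinctness == pytest.approx(1.0)

    def test_identical_top_words_give_coherence_one(self):
        # every word vector identical -> any atom's top words are mutually
        # identical and pairwise cosine is exactly 1
        vocab = Vocabulary(["a", "b", "c"], np.ones(3, dtype=np.int64))
        emb = Embedding(vocab, np.tile([1.0, 0.0], (3, 1)))
        atoms = np.array([[1.0, 0.0], [0.0, 1.0]])
        sc = score_model(AtomDictionary(atoms, np.zeros((3, 2)), 1), emb, top_n=3)
        assert sc.coherence == pytest.approx(1.0)

    def test_duplicate_atom_lowers_distinctness(self):
        rng = np.random.default_rng(13)
        a = np.array([1.0, 0.0, 0.0])
        dup = np.stack([a, a, [0.0, 1.0, 0.0]])
        orth = np.eye(3)
        codes = np.zeros((5, 3))
        d_dup = AtomDictionary(dup, codes, 1)
        d_orth = AtomDictionary(orth, codes, 1)
        from datm.atoms import _distinctness

        assert _distinctness(d_dup) < _distinctness(d_orth)


class TestSelectK:
    def test_single_k_grid_is_chosen(self, planted_embedding):
        X = planted_embedding.unit_vectors()
        _, best, _ = select_k(X, planted_embedding, [6], s=2, iters=3, seed=0)
        assert best == 6

    def test_identical_scores_tie_break_to_smallest_k(self):
        table = pd.DataFrame(
            {"K": [20, 5, 80], "coherence": [0.5] * 3, "distinctness": [0.5] * 3, "r2": [0.9] * 3}
        )
        assert choose_from_scores(table) == 5

    def test_k_at_least_v_rejected(self, planted_embedding):
        X = planted_embedding.unit_vectors()
        with pytest.raises(ValueError):
            select_k(X, planted_embedding, [X.shape[0]], s=2, iters=2, seed=0)
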