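import numpy as np
import pytest

from datm import (
    Embedding,
    SimConfig,
    Vocabulary,
    build_vocabulary,
    generate_corpus,
    plant_space,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small strong-separation synthetic corpus with planted ground truth."""
    cfg = SimConfig(V=300, N=24, K_true=8, docs=200, doc_len=60, n_anchor_pairs=4, seed=42)
    space = plant_space(cfg)
    return cfg, space, generate_corpus(cfg, space)


@pytest.fixture(scope="session")
def planted_embedding(small_sim):
    """Embedding over the small corpus vocabulary using the *planted* vectors."""
    _, space, sim = small_sim
    vocab = build_vocabulary(sim.docs, min_count=1)
    row = {t: i for i, t in enumerate(space.terms)}
    vectors = np.stack([space.words[row[t]] for t in vocab.terms])
    return Embedding(vocab, vectors)


@pytest.fixture(scope="session")
def tiny_embedding():
    """Hand-sized 10-word embedding in 4 dimensions for oracle comparisons."""
    rng = np.random.default_rng(3)
    terms = [f"t{i}" for i in range(10)]
    vocab = Vocabulary(terms, rng.integers(1, 50, size=10))
    return Embedding(vocab, rng.standard_normal((10, 4)))
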