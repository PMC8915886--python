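# datm — discourse atom topic modeling

`datm` discovers latent topics in a corpus by combining topic modeling with
word embeddings: topics are **discourse atoms**, unit vectors in the
embedding space found by sparse dictionary learning, and documents are
mapped onto topics through a generative latent-variable language model.
Because topics, words, and documents all live in one semantic space, the
same tools that measure latent dimensions of meaning in embeddings (for
example a masculine–feminine axis) apply directly to topics.

The package is aimed at computational social scientists and public-health
researchers working with large collections of short administrative
narratives (e.g., mortality-surveillance free text), where themes must be
discovered without prespecified stopword lists or coding schemes and then
related to structured covariates.

## The model

A trained embedding assigns each vocabulary word `w` a vector **w** in
R^N.  Topics are `K` unit-norm atom vectors `a_1 … a_K` such that every word
vector is approximately a sparse linear combination of at most `s` atoms;
the dictionary is learned with K-SVD (orthogonal matching pursuit for the
sparse codes, per-atom rank-1 SVD updates for the atoms).  Candidate `K`
are scored by topic *coherence*, inter-atom *distinctness*, and
reconstruction *R²*.

Text connects to this space through a latent-variable language model: a
discourse (gist) vector `c_t` drifts slowly through semantic space, and the
word emitted at position `t` follows the mixture

```
Pr[w at t | c_t] = α p(w) + (1−α) exp(⟨c̃_t, w⟩) / Z,   c̃_t = β c_0 + (1−β) c_t
```

where `p(w)` is corpus frequency, `c_0` a corpus-wide global component, and
`α`, `β` mixing weights.  The MAP estimate of `c̃_t` for an observed window
`C` is the smooth-inverse-frequency (SIF) weighted sum
`Σ_{w∈C} a/(p(w)+a) · w`.  Subtracting the projection onto `c_0`
(estimated as the first principal component of sampled window embeddings)
leaves the local gist, which is assigned to the nearest atom by cosine:
`argmax_k cos(a_k, c_t)`.  Rolling windows over a document yield its topic
sequence, distribution, and binary presence vector.

Semantic dimensions are built from anchor word pairs (she/he, woman/man,
…) as the normalized mean of normalized difference vectors; a topic's
loading on the dimension is the cosine of its atom with the axis.

A simulator generates corpora *from the same generative model* with planted
atoms, a planted semantic axis, and group labels, so every stage can be
validated against ground truth.

## Worked example

The `datm` console script chains the full pipeline on a synthetic corpus:

```yaml
# example.yaml
seed: 11
outdir: example_out
simulate: {V: 1000, N: 40, K_true: 12, docs: 800, doc_len: 80, n_anchor_pairs: 6}
vocab: {min_count: 3}
embedding: {dim: 40, window: 5, epochs: 4}
atoms: {K: 12, s: 3, iters: 15, top_n: 7}
sif: {a: 0.001, window_size: 10, stride: 5}
```

```
$ datm run-all --config example.yaml
...
INFO associate: spearman rho=0.818 p=0.0011 over 12 topics
INFO run-all recovery: {'mean_abs_cosine_to_planted': 0.8819..., 'window_accuracy': 0.7691, 'n_windows': 12000}
```

`recovery.json` reports how well the fitted atoms match the planted topics
(mean absolute cosine after Hungarian matching, 0.88 here) and the fraction
of the 12,000 rolling windows assigned to the correct planted topic (0.77).
`loading_prevalence.tsv` holds the Spearman correlation between each
topic's loading on the planted gender-like axis and its prevalence ratio
between the two document groups — ρ = 0.82 (p = 0.0011) above, i.e. topics
that sit on the tilted pole of the axis are indeed the topics
over-represented in the tilted group.  `topics.tsv` lists each topic's
nearest terms with cosines (the human-readable topic summaries), and
`loadings.tsv` ranks topics along the axis.

Every stage is also available as a library function
(`plant_space`/`generate_corpus`, `build_vocabulary`, `train_embedding`,
`ksvd_fit`/`select_k`, `document_topics`, `build_dimension`,
`prevalence`/`topic_logit`) and as individual subcommands
(`simulate`, `preprocess`, `embed`, `fit-atoms`, `select-k`, `assign`,
`dimension`, `associate`).

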