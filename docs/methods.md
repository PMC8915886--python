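# Methods

This note records the model implemented by `datm`, the design decisions
taken where the method leaves room, the study conditions emulated by the
simulator, and the numerical conventions that make runs reproducible.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Generative model and gist estimation

The corpus model is a log-linear latent-variable language model.  A
discourse ("gist") vector `c_t` moves slowly through the N-dimensional
semantic space; the word emitted at position `t` is drawn from

    Pr[w | c_t] = α p(w) + (1−α) exp(⟨c̃_t, w⟩) / Z_c̃,
    c̃_t = β c_0 + (1−β) c_t,   c_0 ⊥ c_t,

where `p(w)` is the unigram frequency, `c_0` the corpus-wide global
component, and `Z` the normalizer over the vocabulary.  For an observed
window `C` the MAP estimate of the combined context is the
smooth-inverse-frequency (SIF) sum `Σ_{w∈C} a/(p(w)+a) · w`, with the
single smoothing constant `a = (1−α)/(αZ)` treated as one tunable.

* `a` defaults to `1e-3`, the standard SIF operating range (`1e-3`–`1e-4`).
* `c_0` is estimated once per run as the first right singular vector of an
  (uncentered) stack of window embeddings — up to 10,000 windows sampled
  with the run seed — with sign fixed so the largest-magnitude coordinate
  is positive.  Only this first component is removed; removing further
  components is available (`estimate_global` on residuals) but off by
  default.
* Rolling windows are fixed-length token spans: `window_size` 10 tokens,
  `stride` 5 (50 % overlap).  A document shorter than one window is a
  single window; a trailing partial window is kept only if at least
  ⌈window_size/2⌉ of its tokens are in-vocabulary.  Sentence windows can be
  emulated by pre-segmenting the input.
* Windows whose gist is exactly zero (all tokens out of vocabulary) get a
  sentinel topic id (−1) that is kept in the sequence but excluded from the
  distribution and presence vectors.  Topic presence is binary —
  "assigned to at least one window" — with an optional minimum window
  count (default 1).
* Assignment ties (two atoms with identical cosine) resolve to the lowest
  topic id; `nearest_words` ties resolve to the lowest vocabulary index.

## Dictionary learning

Atoms are learned by K-SVD on the unit-normalized word-vector matrix.  The
sparse-coding stage is orthogonal matching pursuit (OMP) with a full
least-squares refit after each greedy selection, so the residual stays
orthogonal to the selected span; the dictionary update is the per-atom
rank-1 SVD of the residual restricted to the atom's current users.  Atoms
with no users are re-seeded from the worst-reconstructed word vector (the
count is logged).  Each atom's sign is flipped so its largest-|coefficient|
word loads positively, removing the SVD sign ambiguity from the top-word
lists.  The dictionary is initialized from `K` distinct data rows chosen by
the run seed; the whole fit is deterministic given that seed.

Greedy OMP equals exhaustive best-subset search only in specific regimes,
and the test suite checks the equivalence exactly there: (a) orthonormal
dictionaries, where greedy selection with refit provably attains the
best-subset optimum for every input, and (b) incoherent near-orthogonal
overcomplete dictionaries with exactly sparse in-model inputs, where OMP
provably recovers the support.  On generic random inputs over coherent
dictionaries greedy pursuit can be suboptimal; that is a property of the
algorithm class, not a defect of this implementation.

Defaults: sparsity `s = 5` per word, 20–30 alternations for routine fits
and up to 60 when exact planted-dictionary recovery is the goal (the
alternation converges but can stall near a local minimum on a small budget).
Model selection
fits a grid of `K` and reports three metrics per fit:

* **coherence** — mean over atoms of the mean pairwise cosine among the
  atom's `top_n` nearest words (embedding-internal, `top_n` default 10);
* **distinctness** — 1 − mean pairwise |cosine| among atom vectors;
* **R²** — 1 − ‖X − codes·atoms‖²_F / ‖X‖²_F, uncentered because word
  vectors have no natural origin.

The default chooser min-max normalizes each metric across the grid
(constant metrics count 0.5) and takes the `K` with the highest mean,
breaking ties toward the smallest `K`; the full table is always emitted so
users can apply a different rule.

## Word embedding

Training uses a minimal seeded skip-gram-with-negative-sampling trainer
written on numpy: symmetric window (default 5), 5 negatives drawn from
`p(w)^0.75`, learning rate decaying linearly from 0.05 to 0.0005,
mini-batches of 1024 pairs with scatter-add gradient accumulation,
single-threaded and bitwise reproducible from the seed.  Input vectors
(`w_in`) are returned.  Raw vectors feed the SIF sums; a unit-normalized
copy feeds K-SVD (dictionary learning on the unit sphere).  Externally
trained vectors in word2vec text format can be loaded in place of the
built-in trainer; serialization uses 17 significant digits so a save/load
round trip is exact.

## Preprocessing

Tokenization lowercases and keeps runs of `[a-z0-9_']`; underscores are
preserved so merged phrases stay single terms.  No stopword list is used —
frequent words are down-weighted by the SIF weights instead.  Phrase
merging scores adjacent pairs by `(count(ab) − δ) / (count(a)·count(b))`
times the current vocabulary size against a threshold, greedily joining
qualifying pairs left-to-right; counts are re-estimated each pass (default
2 passes), so multiword terms can grow.  The vocabulary (default
`min_count` 5) and its probabilities `p(w)` are computed on the post-merge
corpus so the SIF weights match the tokens actually embedded.

## Semantic dimensions

An axis is the normalized mean of normalized per-pair differences
`v(pole_b) − v(pole_a)` over anchor pairs; pairs with out-of-vocabulary
anchors are skipped and reported.  A PCA-over-differences variant was
considered and rejected as the default: the mean of differences is simpler,
has a deterministic sign (pole_a → pole_b), and the two agree closely when
pair differences are consistent.  Topic loading is the cosine between atom
and axis; positive loadings point to pole_b by convention.  The shipped
gender pair list (she/he, woman/man, her/him, female/male, mother/father,
daughter/son, wife/husband, sister/brother) is data, not code, and any
other binary connotation can be supplied the same way.

## Simulator: study conditions

The simulator emits corpora from exactly the model above, with planted
ground truth for every stage.  Defaults (the package's standard test
scale, minutes on one CPU): vocabulary `V = 2000`, dimension `N = 50`,
`K_true = 20` planted topics, 2,000 documents of 100 tokens.

* **Space.** `K_true + 2` orthonormal directions from a QR decomposition
  give the atom base, the semantic axis, and `c_0`.  Atom `k` is the unit
  vector along `q_k + pole_k · axis_gap · axis`, with poles alternating ±1
  and `axis_gap = 0.4`.  Each regular word loads on one dominant atom
  (balanced assignment) with coefficient 1 plus, when `s_true > 1`, up to
  `s_true − 1` Gaussian side-coefficients, plus optional isotropic noise.
  Unigram probabilities are Zipfian (exponent 1) over a random permutation
  of the vocabulary.  Eight anchor pairs sit at ±0.8 along the axis and
  give the dimension builder in-vocabulary poles.
* **Documents.** A balanced binary group label tilts the dominant-atom
  choice by `exp(±group_effect·pole/2)` with `group_effect = 1.2`.  The
  gist starts at the dominant atom and follows the mean-reverting walk
  `c_{t+1} ∝ (1−drift)·c_t + drift·(atom + η)` with unit-norm Gaussian `η`
  projected off `c_0` (keeping `c_0 ⊥ c_t`) and `drift = 0.05` — a slow
  walk that stays near the document's theme.  Emission mixes frequency and
  context with `α = 0.1`, `β = 0.2`; the partition function is computed
  exactly over the synthetic vocabulary.
* **Emission scale.** With unit-norm planted vectors, `⟨c̃, w⟩` lies in
  [−1, 1] and the exponential term would be nearly uniform over 2,000
  words, so no setting of α/β/drift could produce topically concentrated
  text.  The model therefore carries an explicit scale,
  `gist_strength = 6.0`, multiplying the inner products (equivalently, a
  word-vector norm scale).  The default was set so that roughly three
  quarters of a document's tokens come from its dominant topic — the
  strong-separation regime the validation suite targets.
* **Truth.** The per-token truth is the planted atom nearest the current
  gist; per-window truth is the majority vote over the window (ties to the
  lowest id).  Recovery is scored by Hungarian matching on |cosine| between
  fitted and planted atoms.  When the fitted dictionary lives in a
  *trained* space, planted atoms are mapped there first as the normalized
  mean of each topic's trained word vectors (`empirical_atoms`).

What the simulator does **not** emulate: syntax, morphology, named
entities, document-length variation, misspellings, or the narrative style
of real mortality-surveillance text.  Passing tests therefore demonstrate
that the pipeline recovers structure generated by its own model family at
realistic sizes — a necessary correctness check — not that real narratives
satisfy the model's assumptions.

## Downstream description

Prevalence tables count documents with a topic present per group;
prevalence ratios with a zero reference cell are reported as undefined and
excluded (with a count) from correlations rather than continuity-corrected.
The loading-vs-prevalence association uses Spearman rank correlation
(average ranks, large-sample two-sided p), which is invariant to monotone
transforms, so raw and log ratios give identical values.  Logistic
regressions of topic presence delegate maximum-likelihood fitting to
statsmodels; this module owns covariate coding (dummy coding against
documented reference levels), adjusted odds ratios with Wald 95 %
intervals, and explicit flags for non-convergence and degenerate outcomes.

## Problem sizes and reproducibility

The validation suite and `scripts/acceptance.py` use: 200 sparse-coding
oracle instances (K ≤ 8, s ≤ 3); a planted dictionary fixture with
`V = 1000`, `N = 50`, `K = 20`, `s = 3` at noise 0 and 0.05; the default
2,000-document corpus for SIF checks, end-to-end recovery (with a freshly
trained 50-dimensional embedding), and five-seed association checks;
n = 10,000 and 20 × n = 5,000 for regression calibration; and a reduced
configuration (V = 250, 100 documents) for byte-identity of repeated runs.
All randomness in library, CLI, and scripts flows from a single integer
seed; runs are single-threaded.  Artifact TSVs carry a `# datm` header with
the config hash and seed; vectors, atoms, and codes serialize at 17
significant digits so the stagewise CLI path and the in-process `run-all`
path produce identical bytes.

## Known limitations

* The SGNS trainer is deliberately minimal (no frequent-word subsampling,
  no dynamic window, no hierarchical softmax); it is adequate for the
  simulator's vocabulary sizes but slower and less tuned than optimized
  implementations for large real corpora — where externally trained
  vectors can be loaded instead.
* K-SVD cost grows linearly in `V · iters · K`; the per-row OMP loop
  dominates for `K` in the hundreds.
* Coherence is embedding-internal (cosine among top words), not a
  co-occurrence NPMI; with very small vocabularies the `top_n` neighborhood
  of different atoms can overlap, compressing coherence differences across
  `K`.
* Hard nearest-atom assignment ignores the margin to the runner-up atom; a
  soft assignment is intentionally out of scope.
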