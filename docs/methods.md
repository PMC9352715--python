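# Methods

## Problem setting

The package targets next-item recommendation on implicit-feedback
interaction data derived from scientific literature: users are paper
authors, items are scientific entities (ChEBI chemical compounds, or open
star clusters), an interaction means the author mentioned the entity in a
paper, every rating is 1, and the publication year orders each author's
items into a sequence. Such data are extremely sparse (a 2.5k × 16k
chemistry matrix is ~99.7% empty) and strongly long-tailed: a few entities
collect most mentions. The central idea implemented here — sequence
enrichment (SeEn) — attacks the sparsity by inserting, after each item of
a sequence, the n items most similar to it, before a sequence-aware model
is trained.

## Data model and sequence construction

An interaction is `<user, item, rating=1, year>` with an optional item
name. Sequences are built per user by sorting on `(year, item id)`; the
data do not define an order within a year, so the ascending-id tie-break
is a determinism choice, with a seeded-random alternative for sensitivity
checks. Duplicate user–item pairs collapse by default to their earliest
year (`dedup="first"`), matching the unique-pair reading of the sparsity
formula `1 − pairs/(users × items)`; a `keep-all` policy is available
because mention data can legitimately repeat. Quality filters: users with
fewer than 20 interactions are dropped (cold start), and sequences can be
capped at a maximum length — the cap keeps the most recent suffix, because
leave-one-out evaluation hides the final item and the tail must survive.
Dataset statistics report sizes, the year span, sparsity, and the share of
ratings taken by the top 1/5/10% of items (the long-tail profile), with
the percentile item count rounded up.

## Item–item similarity

Two backends produce the symmetric item–item scores that drive
enrichment:

* **Semantic similarity over an is_a ontology** (chemistry). The OBO
  reader keeps only `[Term]`, `id`, `name`, `is_a`, `is_obsolete`;
  obsolete terms and their edges are dropped, cycles and dangling targets
  are errors. Information content is intrinsic by default,
  `IC(t) = −ln((desc(t)+1)/N)` in nats, so a root has IC 0 and the
  package needs no external corpus; corpus IC from annotation counts
  (propagated to ancestors) is available. Pair scores use the most
  informative common ancestor (MICA, self included, IC ties broken by
  ascending id): Resnik `IC(MICA)`, Lin `2·IC(MICA)/(IC(a)+IC(b))` (0
  when both ICs vanish), and Jiang–Conrath folded from a distance into
  `1/(1+d)` so that all three metrics orient "more similar = larger" on
  [0, 1]. Plain MICA is used rather than disjunctive-ancestor
  refinements; externally computed similarity databases (e.g. DiShIn
  output) can be loaded through the TSV table format instead.
* **Cosine over numeric features** (astronomy). Per-member feature rows
  (e.g. member stars' longitude, latitude, parallax) are mean-aggregated
  into one vector per item; cosine scores are kept unclamped in [−1, 1]
  and zero vectors are rejected.

Either backend is materialised as a neighbour table: for every item the
top-n neighbours by (score descending, id ascending), stored once per
undirected pair. Tables are incomplete in general — an anchor without
known neighbours simply contributes nothing.

## Sequence enrichment

`enrich_sequence` inserts, immediately after each original item, its top-n
neighbours in descending similarity order. Injected items carry an
origin flag and their anchor, inherit the anchor's year and the unit
rating, and may duplicate items already in the sequence (no
deduplication — the enriched length is exactly `(n+1)·L` under a complete
table). Stripping injected items recovers the source sequence, which is
both a tested invariant and the serialisation contract of the
`origin`-column CSV format. The random-injection control draws n items
uniformly (without replacement, anchor excluded) per anchor position.

Enrichment is applied to training prefixes only. The validation item
(second-last) and test item (last) are never enriched: injecting
neighbours of the hidden target would leak it into the model input. When
training on sequences enriched with n items per anchor, the model-side
window grows from `base_max` to `base_max × (n+1)` so the injected items
do not crowd out the original context.

## Recommenders

* **Most-Pop** ranks items by global training rating count (ties by id);
  user and sequence order are irrelevant by construction.
* **Implicit-feedback ALS** factorises the unique-pair preference matrix
  under the confidence-weighted objective
  `Σ c_ui (p_ui − x_uᵀy_i)² + λ(‖X‖²+‖Y‖²)` with `p_ui = 1` iff observed
  and `c_ui = 1 + α r_ui`. Each sweep solves the per-user and per-item
  ridge systems exactly (Gram-matrix shortcut over observed entries), so
  the objective is non-increasing sweep over sweep — verified against a
  dense oracle. Defaults: f=64, λ=0.01, α=40, 15 sweeps, seeded normal
  init (scale 0.01).
* **Masked-item transformer.** A bidirectional encoder over item +
  learned absolute position embeddings: L blocks of multi-head
  self-attention (no causal mask, additive −1e9 bias on PAD keys) and a
  GELU feed-forward, post-layer-norm residuals, output logits through the
  tied item-embedding matrix plus a bias. Training masks positions two
  ways: a cloze instance (each live position masked independently with
  probability 0.2, at least one), and a next-item instance masking only
  the final position; batches mix the two half and half. Loss is
  cross-entropy at masked positions only, optimised with Adam (lr 1e-3).
  Sequences are left-padded with the suffix kept, so the most recent
  context always fits the window. Prediction appends a MASK after the
  context and reads that position's item distribution (PAD and MASK
  excluded). The implementation is pure numpy with hand-written
  backpropagation, checked against central finite differences in the test
  suite. Defaults (2 layers, 2 heads, d=64, d_ff=128) are a CPU-scale
  reduction of the usual configuration of this model family; at very
  small widths (d≈16) optimisation can stall in a context-independent
  marginal solution, which is why the defaults stay at d=64.

## Evaluation

Leave-one-out per user: last item test, second-last validation, rest
training context. A recommender scores candidates given training prefix
plus validation item; the test item's 1-based rank (ties by ascending id)
yields `HR@k = mean[rank ≤ k]` (equivalently 1 − missRatio) and
`nDCG@k = mean(1/log2(rank+1) · [rank ≤ k])` — with a single relevant
item the ideal DCG is 1, so nDCG@1 ≡ HR@1 and nDCG@k ≤ HR@k. Metrics are
macro-averages (each user weight 1) at k = 1, 5, 10. The default
candidate set is the full catalogue; a sampled policy (test item vs m
popularity-proportional negatives outside the user's training items) is
provided for parity with reference protocols. A test item the scorer
cannot rank counts as a miss and is logged. The grid runner produces one
row per (cell, seed, k) with full provenance, and identical seeds
reproduce identical tables.

## Synthetic data

The generators reproduce the statistical structure of the literature
datasets at desk scale so every component is testable offline:

* **Zipf long tail**: item popularity ∝ rank^(−s), default s = 1.2;
  lengths lognormal-clipped to [20, 80] with mean ≈ 40; years are sorted
  uniform draws per user. At the default 500 users × 1000 items the
  unique-pair sparsity exceeds 90%, matching the regime of the real data.
* **Planted sequential signal**: each user walks the catalogue; with
  probability q the next item is drawn from the current item's top-5
  similarity neighbours, otherwise from global popularity (never
  repeating the current item). q = 0 reduces exactly to the popularity
  generator; q = 0.7 is the benchmark condition.
* **Toy ontology**: a complete is_a tree (depth × branching) plus a
  seeded fraction of extra edges to strictly shallower levels, acyclic by
  construction.
* **Group-structured features**: orthonormal group centroids (QR of a
  random Gaussian matrix) plus isotropic noise, so within-group cosine
  exceeds between-group cosine in expectation, exactly 1 vs 0 at zero
  noise.

What the generators do **not** emulate: author co-publication structure,
item-catalogue growth over years, bursty mention dynamics, or the actual
ChEBI topology. Passing benchmarks here shows that the pipeline recovers
a planted similarity-transition signal and that enrichment interacts with
that signal as designed — not that the same margins would appear on the
real literature corpora.

## The planted-signal benchmark

The condition grid mirrors the method's core comparisons: the masked
model on (a) original order, (b) shuffled order (last two positions
pinned so the evaluation targets are identical), (c) Sim+1 enrichment,
(d) Rand+5 enrichment, plus Most-Pop. Expected qualitative orderings,
asserted by sign test across 3 seeds: sequential > shuffled, Sim+1 ≥
original, Rand+5 < original, Most-Pop < masked model.

Problem sizes are the package's own desk-scale choice: 150 users, 300
items, 25 latent feature groups (noise sd 0.1), q = 0.7, sequence lengths
20–50 (mean ≈ 30), base window 15 (so Rand+5 trains on windows of 90),
model 2 × 2 × 64 with d_ff = 128, 400 Adam steps at batch 32, full-catalogue
ranking. One condition grid over 3 seeds runs in roughly ten minutes on a
single CPU; the shuffled-order ablation reuses the same split because
shuffling pins the last two positions.

## Numerical and design notes

* All id ordering is "numeric if possible, else lexicographic", applied
  consistently to tie-breaks in sorting, ranking, neighbour lists and
  MICA selection.
* One global seed fans out to per-stage, per-user streams via
  crc32-tagged `SeedSequence` derivation, so stages are independently
  reproducible and per-user shuffles are exchangeable.
* Natural log throughout information content (it cancels in Lin and fixes
  Resnik/JC scales); log base 2 in DCG.
* Shuffling pins the last **two** positions (test and validation) so
  validation-based decisions stay comparable across ablations; `fix_last=1`
  recovers the weaker guarantee.
* Degenerate inputs: users shorter than 3 are excluded from splits with a
  warning; empty datasets are an error for statistics; `n = 0` enrichment
  is the identity; a zero feature vector is rejected rather than silently
  scored.
* Known limitations: the numpy transformer is single-threaded and
  CPU-bound (minutes per benchmark run, not suited to 100k-interaction
  corpora); plain MICA ignores multiple disjunctive ancestors; the
  sampled-negatives policy and corpus IC are implemented but not exercised
  by the benchmark.
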