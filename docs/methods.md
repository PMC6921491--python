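# Methods

`kgddi` implements a drug–drug interaction (DDI) prediction pipeline in
which drug representations are learned from a biomedical knowledge graph
and candidate drug pairs are classified, together with the evaluation
machinery that makes such claims honest for *paired* data: drug-wise and
pairwise disjoint cross-validation, time-slice evaluation, and a
chi-square diagnostic for split bias.

## Pipeline

1. **Background graph** (`kg_io`). The knowledge graph arrives as
   N-Triples. Known interaction edges (identified by an explicit predicate
   set, e.g. a `ddi-interactor` pattern) are removed before any feature
   learning, so embeddings cannot leak the label being predicted. Literal
   objects are kept as terminal walk tokens but are not entities: they are
   never walk roots and never corruption candidates.
2. **Walk corpus** (`graph_walks`). From each root entity,
   `walks_per_entity` random walks of `depth` edge traversals emit
   alternating entity/predicate tokens (a depth-`d` walk has at most
   `2d+1` tokens). Steps are uniform over outgoing edges; dead ends
   truncate the walk rather than restarting, which leaves co-occurrence
   counts unbiased.
3. **Embeddings** (`embed_models`). Either word2vec-style models trained
   on the corpus (skip-gram or CBOW with negative sampling), or
   translational models trained on the triples (TransE, TransD).
4. **Pair datasets** (`pair_dataset`). A pair's feature vector is the
   concatenation of its two drugs' vectors in canonical (lexicographic)
   order — `2 × dim` features. Negatives are unknown pairs sampled in
   equal number to the positives.
5. **Classification and evaluation** (`experiment`). Logistic regression
   (C = 0.01), Gaussian naive Bayes, or a random forest (200 trees, max
   depth 8) score pairs; AUC, AUPR and F1 are averaged over folds and over
   independently seeded runs.

## Disjoint cross-validation

Traditional k-fold CV partitions *pairs*; the same drug then appears on
both sides of the split and the estimate is optimistic for drugs with no
known interactions. The disjoint scheme instead partitions *drugs* into k
near-equal groups (one shuffle, contiguous blocks). Fold i holds out group
i as the cold-start set and splits the known interactions KDDI into

- `train`    = {(d1,d2) : both drugs existing},
- `drugwise` = {(d1,d2) : exactly one drug cold-start},
- `pairwise` = {(d1,d2) : both drugs cold-start},

which is an exact partition of KDDI. One training set serves both test
sets per fold (k rounds total, versus k within-group plus k(k−1)/2
between-group rounds if the two cold-start scenarios are sampled
separately — `cv2_round_counts` computes the comparison). Grouping is done
on drugs, not on the first pair component, so the partition is identical
no matter how pairs are enumerated. Drugs with no known interactions are
still assigned to groups; they participate in the negative pair space.

Negative sampling is *block-matched*: train negatives are drawn from the
existing×existing block, drug-wise negatives from existing×cold-start, and
pairwise negatives from cold-start×cold-start, always excluding every
known interaction of the full reference set. Sampling negatives from the
whole pair space instead would let test negatives share drugs with
training pairs and silently reintroduce the leakage the split removes.
Every run of an experiment re-draws fold assignment and negatives with a
fresh seed.

Time-slice evaluation trains on an early snapshot of the interaction set
and tests on the pairs added by a later snapshot, split into `n_groups`
random subsets whose scores are averaged.

## Bias-check diagnostic

A drug-level split should hold out *drugs*, not *mechanisms*. The
diagnostic tallies the categorical DDI-type composition of each fold's
training set and combined (drug-wise ∪ pairwise) test set and computes a
Pearson chi-square consistency statistic with expected counts
`n_test × p̂_train` per type, pooling types with expected count below 5
into one residual cell (dof = cells − 1).

Because the training composition is itself estimated from a finite
sample, the raw Pearson sum is inflated by the factor
`1 + n_test/n_train`; the statistic is divided by this factor by default
(`train_as_sample=True`), which keeps the test calibrated for any
train/test size ratio — empirically, on the synthetic preset the per-fold
rejection rate at α = 0.05 is ≈ 0.05–0.07 with the correction and ≈ 0.22
without it. The uncorrected form remains available for comparing a test
sample against a *known* reference composition. Note that even for a
perfectly calibrated test, "p > 0.05 in all k folds" is an event with
probability ≈ 0.95^k per seed; the stable property is calibration, not
any single all-folds outcome.

## Embedding models

**Skip-gram / CBOW.** Standard negative-sampling objectives: skip-gram
scores (center, context) token pairs by the inner product of the center's
input vector and the context's output vector; CBOW replaces the center
input vector by the mean input vector of the context window. Defaults
mirror the common biomedical-KG setting: window 5, 5 epochs, 25 negative
samples, dimension 100, frequent-token subsampling at threshold 1e-3.
Negatives are drawn from the unigram^0.75 distribution. Subsampling
matters more here than in natural text: predicate tokens are a fifth of
the corpus and, untreated, pull every embedding onto a single frequency
direction.

The trainer is plain numpy minibatch SGD (batch 128) with one
implementation-specific choice: within a batch, each parameter row
receives the *mean* gradient over its occurrences rather than the sum.
Hub entities and frequently drawn negatives can occur hundreds of times
per batch; summed updates at any useful rate made the input and output
norms amplify each other and diverge. With mean updates each row moves at
most one learning-rate step per batch, and a larger rate (0.4, linear
per-epoch decay) replaces the many small sequential steps of classic
word2vec. The exact softmax of the models is kept in
`skipgram_probability` / `cbow_probability` (negative sampling is a
training-time approximation only), so normalization can be verified to
1e-9.

**TransE.** A triple (h, r, t) is scored by ‖h + r − t‖ (L2 by default,
L1 available). Training minimizes the margin-ranking hinge
`[γ + d(h+r,t) − d(h',r,t')]₊` with one corrupted triple per true triple
per batch (head or tail replaced with probability ½ by a uniform entity,
resampled on collision). Defaults: dim 100, γ = 1, SGD at rate 0.01,
batch 128, 100 epochs, init uniform in ±6/√dim, relation vectors
normalized once, entity vectors renormalized to unit L2 norm at the end
of every epoch (and after training). Literal-object triples are excluded:
literals are not meaningful corruption candidates.

**TransD.** Each entity and relation carries an embedding vector and a
projection vector; an entity is projected into the relation space as
`e⊥ = r_p (e_pᵀ e) + resize(e, n)`, equivalent to the mapping matrix
`r_p e_pᵀ + I` without ever materializing it (vector operations only).
`resize` zero-pads or truncates when entity and relation dimensions
differ. Projection vectors are initialized randomly: the all-zero
initialization is a saddle point (each projection gradient is a product
with the other, zero, projection vector) from which training cannot
escape. Per-pair hinge losses and analytic gradients for both models are
exposed (`transe_pair_loss_grad`, `transd_pair_loss_grad`) and verified
against central differences to 1e-4 relative error.

## Synthetic data generator

The generator (`synthetic_data`) emulates the *shape* of a biomedical
background graph and interaction set so the full pipeline is exercisable
without external downloads:

- **Graph**: `n_drugs` drug nodes each linked to `attributes_per_drug`
  distinct attribute nodes (targets/enzymes/pathway-like entities)
  through uniformly chosen typed predicates. Attribute popularity follows
  a Zipf(1.0) law: real pharmacology is heavy-tailed — a handful of hub
  targets and metabolizing enzymes are shared by many drugs. Under
  uniform popularity, 5 attributes from a pool of 1500 would almost never
  be shared at desk scale and no learnable structure would exist.
- **Interactions**: each canonical pair interacts independently with
  probability `sigmoid(logit(base_rate) + signal_strength·shared +
  b(d1) + b(d2))` where `shared` is the shared-attribute count and `b` is
  a latent per-drug propensity, `b ~ N(0, drug_propensity_sd²)`. The
  shared-attribute term is the graph-visible signal that embeddings can
  capture; the propensity term models the strong degree heterogeneity of
  real interaction networks that curated attributes do *not* explain.
  The propensity term is what pair-level CV can memorize and drug-level
  CV cannot: with `drug_propensity_sd = 0` every informative quantity is
  graph-visible, all schemes converge, and the optimism that disjoint
  evaluation is designed to expose disappears (and, in our measurements,
  the ordering of schemes becomes noise). Defaults: 300 drugs, 1500
  attributes, 4 relation types, 5 attributes/drug, base rate 0.02,
  signal 1.0, propensity SD 1.0 — yielding ≈ 3,300 interactions (≈ 7% of
  pairs, comparable to curated interaction databases).
- **DDI types**: positives receive a type drawn i.i.d. from one fixed
  Zipf-skewed 20-category multinomial, echoing the concentration of real
  interaction mechanisms in a few frequent classes.
- **Snapshots**: an early/late snapshot pair for time-slice evaluation
  keeps a random fraction of pairs as the early set; early ⊆ late by
  construction.

What the generator does **not** emulate: realistic ontology structure
(attribute–attribute edges, hierarchies), scale-free drug degree in the
*graph* (only in the interaction network via the propensity term),
drug-specific type composition (types are i.i.d., which is exactly what
the bias check's null requires), and the scale of real releases (millions
of triples, tens of thousands of interactions). Passing tests therefore
demonstrate correctness of the machinery and the *direction* of the
evaluation-scheme effects, not the headline performance levels reachable
on real curated graphs.

## Evaluation metrics and experiment protocol

AUC is computed as the probability that a random positive outranks a
random negative (ties count ½), AUPR as the step-interpolated area under
precision–recall, F1 at a fixed probability threshold of 0.5 (a
configurable convention; the threshold is not tuned). Reported scores are
means over folds and over `n_runs` seeded runs; in the disjoint scheme the
drug-wise and pairwise test sets are reported per fold (in-sample
training metrics optionally via `include_train`). A pair-identity audit
asserts in every run that no test pair's feature row was seen in
training.

The test suite and the acceptance script run everything at desk scale:
300 drugs, skip-gram dimension 50, depth-2 walks, 100 walks per entity,
10-fold CV, 10 runs for the scheme-ordering experiment — sizes chosen so
the full study runs on a laptop-class single core in minutes while
keeping every per-fold test set large enough for stable rank metrics.

## Known limitations

- The word2vec trainer is a faithful but compact reimplementation; it is
  not optimized for multi-million-token corpora (no hierarchical softmax,
  no multi-threading — by the same token, runs are bit-reproducible).
- TransE/TransD use fixed learning rates; no early stopping or validation
  of embedding quality beyond the trend and separation tests.
- The negative-sampling rejection loop falls back to exhaustive block
  enumeration when a block is dense; for pathological cases (nearly all
  pairs known) it raises rather than silently under-sampling.
- Time-slice evaluation draws test negatives from the late snapshot's
  unknown pairs; if the late universe is much larger than the early one,
  those negatives may involve drugs unseen in training, mixing cold-start
  difficulty into the time-slice estimate.
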