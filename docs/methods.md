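# Methods

This note records the modelling choices behind `pairprompt`: what is
computed, which knobs matter, what the synthetic benchmark does and does
not emulate, and where the design was genuinely open.

## Pipeline

**Graph.** Interaction tables (TSV: `entity_a_id, entity_a_type,
entity_b_id, entity_b_type, interaction_type[, label]`) are turned into an
undirected, unweighted heterogeneous graph whose nodes are unordered entity
pairs. Entity identity is the tuple `(id, type)` — two entities with the
same id but different types never match. Pairs are canonicalised by
`(type, id)` order so `(a, b)` and `(b, a)` collapse to one node. Per
interaction type at most `per_type_cap` pairs (default 10 000) are kept by
seeded uniform subsampling. An edge joins two pair nodes iff they share at
least one component entity; the rule is applied across interaction types as
well, which is what couples the tasks together. Edges are found by hashing
entities to incident-node lists (linear in nodes + edges); an O(n²) scan
exists only as a test oracle. Labels ride along on nodes and are ignored by
construction and pre-training — verified bitwise in the tests.

**Encoder.** A K-layer GIN (default K = 3, hidden width 16) over learnable
per-node features (default width 32, seeded standard Gaussian init,
linearly projected to the hidden width). There are no measured node
attributes on entity pairs, so the feature table is itself a parameter,
which makes pre-training transductive. Each GIN MLP is two affine maps with
a ReLU between; ε is learnable per layer, initialised 0. Downstream
consumers use the concatenation of all K layer outputs, so representations
have width `hidden × K = 48` — this is also the prompt width.

**Subgraphs and readout.** The δ-subgraph of a node is its
breadth-first ball of radius δ (default δ = 1; one hop keeps subgraphs
small and makes the pre-training and prompt readouts cheap and consistent).
The `sum` readout adds the centre representation to the sum over members;
since the centre is a member it is counted twice. That double counting is
kept deliberately (a `center_once` switch exists for sensitivity checks).
`feature_weighted_sum` right-multiplies the sum by a square matrix `W`;
`linear_mean` averages the same multiset (denominator = members + 1) before
applying `W`. The named mean-then-map form of `linear_mean` is an
interpretation — only its name is conventional, not its formula — and is
documented as such.

**Contrastive pre-training.** Anchors are drawn uniformly from nodes with
at least one neighbour, one triplet per eligible anchor per epoch;
positives are uniform neighbours; negatives follow one of three rules:

* `random` — uniform over non-neighbours;
* `community` — uniform over non-neighbours outside the anchor's Louvain
  community (modularity partition, seeded);
* `degree` — non-neighbours outside the anchor's degree tertile, sampled
  with weight 1/(1 + degree), falling back to all non-neighbours when the
  other tiers are empty.

The loss is the two-candidate softmax cross-entropy of cosine similarities
at temperature τ (default 1.0; cosine because the objective is
temperature-scaled and scale-free). Optimisation: Adam, learning rate 1e-3,
decoupled weight decay 1e-4, 200 epochs. 200 rather than a smaller number
because on the desk-scale benchmark the loss and the contrastive margin are
still improving steeply at epoch 100 and have flattened by 200; the stage
costs seconds either way.

**Prompt tuning and classification.** The encoder is frozen (checkpoint
digests are asserted unchanged). Per task a prompt `p` (init all-ones, i.e.
the identity readout, so tuning starts exactly at pre-training behaviour)
gates every member representation element-wise; `W`, when the strategy has
one, is treated as part of the prompt and trained with it (init identity).
Element-wise gating commutes with the linear aggregation, so the
implementation gates the precomputed plain readouts — mathematically
identical and much cheaper. Bridges are the class means of the prompted
representations of the few-shot examples and are recomputed at every
optimisation step because they depend on the current prompt (a frozen-
bridge mode exists but is off by default). The tuning loss is the summed
two-class softmax cross-entropy against the bridges at the shared τ;
optimisation is Adam, 100 steps, learning rate 1e-2 — enough to converge on
tens of examples. Classification is nearest bridge by cosine; an exact tie
is called negative; the reported score is the two-way softmax probability.
The package default readout for downstream tasks is
`feature_weighted_sum`, the most expressive of the three; `sum` and
`linear_mean` are compared explicitly by `compare_strategies`.

**Evaluation protocol.** Per task, labelled nodes are split into 10
stratified folds. For each fold the evaluation set is the held-out fold and
the tuning set is a fresh balanced sample from the other nine folds with
⌈k/2% of the task's labelled count⌉ examples per class (so k = 1% of a
500-pair task means 3 + 3 examples). Accuracy is the headline metric;
AUROC is carried as a supplementary column. The composition of 10-fold CV
with the k% few-shot rule is under-determined in general; the composition
used here (folds for evaluation, per-fold balanced k% subsample of the
remainder for tuning) is fixed and seed-controlled. Ablations share splits
exactly: `no_pretrain` keeps the prompt machinery over a frozen random
encoder; `no_prompt` fits a logistic-regression head on the plain sum
readouts of the tuning set.

## Synthetic benchmark

The generator emulates the *shape* of multi-task association data: typed
entities, several interaction types sharing entities, balanced labels. Its
planted structure is a logistic latent-factor interactome: entity latent
vectors `u ~ N(0, I_d)` (d = 8) and scalar activities `α ~ N(0, 2²)`; a
pair truly interacts with probability
`σ(b0 + α_a + α_b + (1.5/√d)·u_a·u_b)`, with `b0` bisected per task so the
interactome density is 0.25. A task's positives are sampled from the
interacting pairs with observation bias `exp(2(α_a + α_b))` — mirroring the
well-documented concentration of curated interaction databases on famous,
promiscuous entities — and its negatives uniformly from non-interacting
pairs, 500 pairs per task at a 50:50 ratio, after which labels flip at the
noise rate (default 0.1). Four tasks over drugs, proteins, diseases and
side effects give ≈ 2 000 pair nodes.

Consequently positives concentrate around active, latently compatible
entities and share component entities with each other, forming a dense
region of the pair graph, while negatives are scattered random
combinations — exactly the structural asymmetry the shared-entity edge rule
and contrastive objective presuppose. That is a *modelling choice*, not an
empirical claim: passing the benchmark shows the pipeline recovers this
kind of planted hub/affinity structure from a handful of labels; it does
not show performance on real pharmacological data, which has chemistry,
task-specific biology, and far larger, sparser graphs. The generator also
omits entity features, directed or weighted evidence, and dataset-specific
degree distributions.

`sharing_fraction` controls entity overlap between tasks of the same type;
0 gives entity-disjoint tasks. The transfer experiment uses a single graph
holding two disjoint task groups (drug tasks sharing drugs, substituent
tasks sharing substituents; 250 pairs per task), so entity-sharing and
entity-disjoint task pairs are contrasted under the same encoder. Prompts
there are tuned harder (300 steps, lr 5e-2, k = 10%) so they actually leave
the all-ones initialisation and become task-specific before being compared
or transferred; transfer reuses the source prompt unchanged and recomputes
only the target's bridges from the target's few-shot set.

## Numerical and degenerate-input choices

* Reverse-mode autodiff on numpy arrays backs both training stages; all
  gradients are finite-difference-checked in the test suite. Softplus is
  computed via `logaddexp` for stability.
* Cosine similarity raises on zero-norm vectors rather than returning 0.
* Sampling is everywhere `numpy.random.Generator`-based and seeded;
  neighbour lists are sorted before sampling so results do not depend on
  set-iteration order. Identical inputs and seeds reproduce graphs,
  checkpoints and reports bitwise.
* A fully connected graph admits no contrastive negatives and is rejected;
  anchors without an eligible negative under a strategy are skipped with a
  warning.
* Intercept calibration is 200-step bisection on [-30, 30]; failure to
  reach the target rate within 1e-3 raises rather than silently drifting.
* Empty classes (bridges), empty few-shot sets, width mismatches and
  unknown entity types raise informative errors at the boundary.

## Known limitations

* Transductive features: the learnable feature table is tied to the node
  set, so unseen pairs require rebuilding the graph and (at minimum)
  re-initialising their features.
* Full-graph message passing; fine at the intended scale (10⁴ nodes), not
  engineered for millions of pairs.
* The nearest-bridge classifier is scale-blind (cosine); signals carried
  only in representation magnitude (e.g. raw degree) are invisible to it,
  which is the principal gap to the logistic-regression ablation head.
* Exactly one negative per anchor (no multi-negative InfoNCE) and no graph
  augmentations, by design.
* Prompt transfer recomputes target bridges; transferring bridges as well
  is not supported.
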