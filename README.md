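# pairprompt

Few-shot multi-task graph prompt learning over heterogeneous entity-pair
association graphs.

## The problem

Drug discovery generates many *association prediction* tasks — does this
drug bind that protein, treat that disease, cause that side effect? Labels
are expensive, so each task usually has only a handful of annotated pairs.
`pairprompt` implements a pipeline that shares structure across such tasks:

1. **Entity-pair graph.** Every candidate pair (e.g. a drug and a protein)
   becomes a node of a heterogeneous graph `G = (V, E, A, R)`; two pair
   nodes are joined by an undirected edge whenever they share a component
   entity. Association prediction becomes binary node classification.
2. **Self-supervised pre-training.** A K-layer GIN encoder

   `h_v^k = MLP_k((1 + ε_k) h_v^{k-1} + Σ_{u∈N(v)} h_u^{k-1})`

   is trained with subgraph-contrastive learning: for an anchor `v`, a
   connected node `m` and an unconnected node `n`, minimise

   `L = −ln exp(sim(s_v,s_m)/τ) / Σ_{c∈{m,n}} exp(sim(s_v,s_c)/τ)`

   where `s_v` is the readout (default: sum with the centre counted twice)
   of the δ-subgraph of `v` over the concatenated layer states, and `sim`
   is cosine similarity. No labels are consulted. Three negative-sampling
   strategies are available: random, community-aware (Louvain) and
   degree-stratified.
3. **Prompt tuning.** The encoder is then frozen. For each downstream task
   `z`, a learnable prompt vector `p^(z)` (width = hidden_dim × K) gates
   every member representation element-wise during readout,
   `s_v = READOUT({p^(z) ⊙ h_u})` (optionally followed by a weight matrix
   `W` — the feature-weighted-sum readout, the package default). The k%
   labelled pairs of the task define two *virtual task bridges*
   `B_T, B_F` — class means of the prompted representations — and the
   prompt is tuned to minimise the two-class softmax cross-entropy of each
   labelled pair against the bridges. A query pair takes the label of the
   nearer bridge (cosine; ties → negative).

Because prompts are tiny (tens of parameters), the method adapts to a new
task from single-digit labelled examples, and prompts can be transferred
across tasks that share entities.

## Worked example

A synthetic multi-task benchmark with planted structure ships with the
package (no downloads needed):

```python
import pairprompt as pp

bench = pp.generate_benchmark(pp.GeneratorConfig(seed=0))
model = pp.GraphPromptModel.from_benchmark(bench, seed=0)
results = model.fit(seed=0)          # contrastive pre-training
print(results.summary())

graph = model.graph
report = results.evaluate_task(
    graph.labeled_nodes("drug-protein"), "drug-protein", k_pct=1.0, seed=0
)
print(report.summary())
```

Output:

```
Graph prompt model — contrastive pre-training results
=====================================================
nodes: 2000   edges: 56609
encoder: GIN x3, hidden 16, input 32, delta 1
representation width: 48
strategy: random   tau: 1.0   epochs: 200
loss: 0.6352 -> 0.4614
contrastive margin: +0.1346 -> +0.6554

task=drug-protein k=1.0% strategy=feature_weighted_sum accuracy=0.582 +/- 0.120 (10 folds)
```

The pre-training loss falls from ln 2 (chance) and the contrastive margin —
mean `sim(s_v, s_m) − sim(s_v, s_n)` — rises to ≈ 0.66, showing the encoder
has learned the shared-entity structure. The evaluation line is a 10-fold
cross-validated accuracy in which each fold tunes a prompt on only 1% of
the task's labels (3 positive + 3 negative pairs) and classifies the
held-out fold; 0.58 ± 0.12 on six labelled examples is well above the 0.5
chance level of this noisy benchmark (averaged over tasks and seeds the
full pipeline reaches ≈ 0.62; see below).

The same pipeline is scriptable from the shell:

```bash
pairprompt simulate --seed 0 --out bench/
pairprompt build --interactions bench/interactions.tsv --cap 10000 --seed 0 --out graph/
pairprompt pretrain --graph graph/ --strategy random --seed 0 --out encoder.npz
pairprompt eval --graph graph/ --ckpt encoder.npz --tasks all --k-pct 1 --out report/
```

## Layout

| module | contents |
| --- | --- |
| `graph_construction` | interaction-table parsing, pair nodes, shared-entity edges |
| `encoder` | GIN layers, δ-subgraphs, readout strategies, checkpoints |
| `pretrain` | triplet sampling strategies, contrastive loss, training loop |
| `prompt` | prompt vectors, task bridges, tuning, classification, transfer |
| `evaluation` | few-shot splits, 10-fold CV, ablations, strategy sweeps |
| `synthetic_data` | planted-structure benchmark generator with provenance |
| `experiments` | reproducible desk-scale experiment drivers |
| `model` | `GraphPromptModel` / `PretrainResults` / `PromptResults` facade |
| `cli` | `pairprompt simulate / build / pretrain / eval` |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
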