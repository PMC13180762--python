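# hypertrail

Temporal hypergraph contrastive learning for future hyperedge prediction
over biomedical concept sets.

## The problem

Literature-based hypothesis generation asks which groups of biomedical
concepts (genes, diseases, chemicals, …) will plausibly co-occur in future
publications. `hypertrail` models each article as a *hyperedge* — its
unique set of annotated concepts — stamped with its publication year, so a
corpus becomes a temporal hypergraph `H = {H^(0), …, H^(T)}`. A hypothesis
is a candidate hyperedge at a future time step, and the task is to score
it against deceptively similar fakes.

For a candidate `e^(t)` the model builds a *trail of ideas*: a backward
random walk over concept-overlapping hyperedges
`(e^(t_0), …, e^(t_k))`, `t_0 < … < t_k < t`, approximating the chain of
prior work the candidate extends. Hyperedges are tokenized from three
signals — a local hypergraph convolution over the trail
(`h_i = φ₁({x_j}), x̃_j = φ₂(x_j, {h_i}), z_i = mean x̃_j`), learnable
concept features initialised from random-walk return probabilities on the
bipartite expansion `B = [[0, H], [Hᵀ, 0]]` (walk length `L = 5`), and a
learnable cosine time encoding `ψ(t) = cos(Wt + b)` — then passed through
a causally masked transformer,

    MaskedAttention(Q, K, V) = softmax((QKᵀ + M) / √d_token) V,

whose per-position embeddings are scored by a sigmoid-gated MLP. Training
combines a binary cross-entropy loss over the positive, a *hard negative*
(the positive with 20% of its concepts replaced) and a *global negative*
(a random unrelated hyperedge) with a time-anchored contrastive loss that
pulls the positive's embedding toward the previous step's contextual
embedding and pushes both negatives beyond a margin. See
[docs/methods.md](docs/methods.md) for the full model account.

It is aimed at researchers studying literature-based discovery and
temporal graph learning who want a transparent, CPU-only, fully seeded
reference implementation with a synthetic benchmark; no external data or
services are required.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
python examples/02_trails_and_negatives.py
```

prints (abridged):

```
target hyperedge 51 at t=5, size 14
  trail step t=3: hyperedge 30 (overlap with target: 9 concepts)
  trail step t=4: hyperedge 40 (overlap with target: 11 concepts)

hard negative (r=0.2): shares 11/14 concepts with the target - deceptively similar
global negative: hyperedge 17 from t=1, shares 1/14 concepts - an unrelated hypothesis
```

— the trail's growing overlap shows the planted lineage being recovered
by the overlap-weighted walk, and the hard negative's 11/14 shared
concepts show why a 20% corruption is much harder to reject than a random
hyperedge. `examples/03_train_and_evaluate.py` runs the full
train/evaluate protocol and prints the five evaluation metrics;
`examples/04_consistency_and_ablation.py` reproduces the
coefficient-of-variation and ablation-contribution arithmetic
(CV 4.4%, mean 0.934 from per-dataset AUCs 0.959/0.957/0.887;
global-awareness contribution 0.215 AUC points = 22.4%).

A thin CLI mirrors the pipeline stages:

```bash
hypertrail simulate --out runs/sim
hypertrail prepare runs/sim/hyperedges.jsonl
hypertrail train runs/sim/hyperedges.jsonl --seed 1 --out runs/train
hypertrail report --aucs 0.959,0.957,0.887 --full 0.959 --ablated 0.744
```

Input data is plain JSONL (`{"id": …, "year": …, "concepts": [...]}`) or
TSV (`id <TAB> year <TAB> concept;concept;…`).

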