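# emphcn

Drug repositioning by drug–disease association prediction on a
heterogeneous biological network, combining **hypergraph convolution**
over multi-view drug similarities, **efficient channel attention** to
fuse the views, a **node-and-edge bipartite graph convolution** over
known associations, and a **graph-attention route through proteins**
(drug–protein, disease–protein and protein–protein interaction edges).

## Who this is for

Computational drug-discovery researchers who have, for *M* drugs and
*N* diseases:

* one or more drug–drug similarity matrices `P¹…Pˢ ∈ [0,1]^{M×M}`
  (chemical, target, enzyme, pathway, …),
* a disease–disease similarity matrix `S ∈ [0,1]^{N×N}`,
* a sparse binary association matrix `A ∈ {0,1}^{M×N}`,
* optionally drug–protein / disease–protein edge lists and a PPI graph,

and want ranked candidate indications for each drug (or candidate drugs
for each disease), evaluated under pair-level cross-validation and a
cold-start (novel-disease) protocol.

## The model

Every similarity matrix induces a KNN hypergraph: vertex *v* spawns a
hyperedge containing *v* and its K most-similar neighbors (K = 15 by
default), giving a square incidence matrix H.  Intra-domain embeddings
follow the normalized hypergraph convolution

    X' = ReLU( D_v^{-1/2} H D_e^{-1} Hᵀ D_v^{-1/2} X θ )

applied per view with a shared θ; the S drug channels are fused by
efficient channel attention: per-channel global average pooling, a
shared length-3 1-D convolution, a logistic squash to weights
ω ∈ (0,1)^S, and a weighted channel sum.  Inter-domain embeddings come
from a symmetric-normalized bipartite convolution whose neighbor
messages are gated element-wise by degree-scaled learnable edge
embeddings, plus (optionally) a protein route: graph attention projects
drugs and diseases onto proteins, the merged protein embedding is
smoothed one hop over the PPI graph, and attention projects it back.
Per layer the three routes are summed; two layers (widths k1 = 256,
k2 = 128 by default) are combined by a skip connection, and scores are

    Â = sigmoid( X̂_r X̂_dᵀ ) ∈ (0,1)^{M×N}.

Training minimizes a class-balanced cross-entropy (positive term
up-weighted by λ = |negatives|/|positives|) with Adam, full batch, with
per-epoch edge dropout on the association/protein graphs and feature
dropout on the fused embeddings.  All tensor math runs on a small
reverse-mode automatic-differentiation engine over numpy (validated by
finite differences in the test suite), so the package has no deep
learning framework dependency.

A seeded synthetic-data generator (`emphcn.synthgen`) plants low-rank
logistic structure — factors U, V; associations `Bernoulli(σ(UVᵀ+b))`
with the offset calibrated by bisection to a target density; similarity
views as noisy logistic transforms of the factor correlation kernel;
protein links aligned with per-protein latent directions — so the whole
pipeline is testable without external data.

## Worked example

```bash
emphcn simulate --seed 5 --set m=30 --set n=40 --set p=50 --set s=3 \
    --set rank=3 --set density=0.15 --out-dir demo/net
emphcn train --network-dir demo/net --seed 3 --set k1=32 --set k2=16 \
    --set epochs=300 --set knn_k=10 --set lr=0.01 --set beta=0.1 \
    --set gamma=0.1 --out demo/model.ckpt
emphcn predict --model demo/model.ckpt --network-dir demo/net \
    --query dis003 --top 5
```

The run above prints:

```
wrote network (30 drugs, 40 diseases, 50 proteins) to demo/net
final loss 0.805199; checkpoint at demo/model.npz
rank    id      score
1       drug026 0.858383
2       drug007 0.835736
3       drug029 0.820406
4       drug011 0.552125
5       drug014 0.529534
```

i.e. for disease `dis003` the five highest-scoring drugs not already
known to treat it, with their predicted association probabilities.
The same library calls are available in Python:

```python
from emphcn import SynthConfig, generate_dataset, EMPHCN, small_config
network, truth = generate_dataset(SynthConfig(m=30, n=40, p=50, seed=7))
model = EMPHCN(network, small_config(epochs=200, seed=1))
model.fit()
scores = model.predict()          # (30, 40) probabilities in (0,1)
```

Evaluation (`emphcn evaluate --protocol kfold|novel ...` or
`emphcn.evalcv.cross_validate`) trains a fresh model per fold and
reports AUROC, AUPR, recall, accuracy and F1 with per-fold detail.

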