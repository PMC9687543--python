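# Methods

## Model

The predictor scores every drug–disease pair through two hidden layers,
each of which sums three message-passing routes per domain, followed by
a skip connection and a bilinear logistic score.

**Intra-domain route (hypergraph convolution).** Each drug similarity
view and the disease similarity matrix induce a K-nearest-neighbor
hypergraph: vertex *v* spawns one hyperedge containing *v* itself plus
its K most-similar other vertices, so the incidence matrix H is square
and every hyperedge has degree K+1.  Including the center is a
deliberate choice — without it a vertex cannot recover its own signal
in one hop — and the exclusion variant remains available
(`include_center=False`) for sensitivity analysis.  Neighbor ties are
broken by (similarity descending, index ascending), making construction
deterministic and seed-free.  The convolution operator
`D_v^{-1/2} H D_e^{-1} Hᵀ D_v^{-1/2}` is symmetric with spectrum in
[0, 1] and exact fixed point `D_v^{1/2} 1`; it is precomputed once per
hypergraph since it never changes during training.  A rectifier is
applied between layers (the printed update is linear, but a purely
linear two-layer stack would collapse; the flag `hgcn_activation`
exposes the linear variant).  One weight matrix is shared across the S
drug views per layer (`per_view_weights` switches to independent
weights).  Hyperedge weights are identity.

**Channel attention.** The S per-view drug channels are fused by
efficient channel attention: global average pooling over drugs and
features gives a length-S descriptor, a single shared 1-D convolution
kernel (length 3, zero same-padding so the output length is S for any
S ≥ 1) produces per-channel logits, and a logistic squash gives weights
in (0,1).  Weights are *not* re-normalized to sum to one; the fused
embedding is the raw weighted channel sum.  The kernel is trained
jointly and initialized small-uniform (±0.01) so initial fusion is
near-uniform (ω ≈ 0.5).  With a single view the attention block is
bypassed entirely — scaling the only channel by a logistic weight would
rescale embeddings without selecting anything.

**Inter-domain route (node+edge bipartite convolution).** Edge
information enters as degree-scaled learnable vectors: drug *i*
receives `(Σ_j A_ij)·w` and diseases symmetrically.  Neighbor messages
are gated element-wise by these edge embeddings, normalized by
`1/√(|N_d||N_r|)`, projected across domains and rectified.  With edge
vectors at one and identity projections the pass reduces exactly to a
symmetric-normalized bipartite graph convolution, which is also how the
edge vectors are initialized (ones), so training starts from the plain
GCN and learns feature-wise gates from there.  Nodes with no
inter-domain neighbors receive zero from this route (the aggregation is
a pure sum); the intra-domain term compensates in the layer fusion.

**Protein route (graph attention).** Drug and disease embeddings are
projected onto proteins by single-head graph attention (leaky slope
0.2), merged by feature-axis concatenation followed by a learnable
2F→F projection (the merge must re-enter F-width layers), smoothed one
GAT hop over the PPI graph, and projected back to both domains.  The
smoothed protein embedding is used for both back-projections; the
printed formulation projects the unsmoothed embedding back to drugs
only, and that asymmetric variant is reproducible with
`faithful_eq14=True`.  Proteins need no externally supplied features:
their initial input is the P×P identity, symmetric with the
incidence-matrix initial inputs of drugs and diseases, and after each
layer the protein state is the PPI-smoothed embedding.  GAT parameters
are independent per layer.  Attention destinations with empty
neighborhoods pass their previous embedding through unchanged when the
layer preserves width and receive zero rows when it does not (a
pass-through across widths is undefined).

**Fusion, skip, score.** Per layer the three routes are summed
(protein route zero when the branch is disabled or the network has no
protein layer).  The printed skip connection adds embeddings of widths
k1 and k2, which is dimensionally impossible; a bias-free learnable
k1→k2 projection (one per domain, zero-initialized) is applied to the
first-layer embedding before the sum.  `literal_skip_sum=True` with
k1 = k2 reproduces a literal sum.  Scores are
`sigmoid(X̂_r X̂_dᵀ)`, strictly inside (0,1).

**Initial inputs.** Both branches are seeded with the incidence matrix
of the configured drug view (index 0 by default) and the disease
incidence matrix, so the first-layer weights have per-domain input
widths M and N.

## Loss and optimization

The training objective is the class-balanced binary cross-entropy

    L = −(1/(N·M)) [ λ Σ_{(i,j)∈y} log Â_ij + Σ_{(i,j)∈ȳ} log(1−Â_ij) ],
    λ = |ȳ|/|y|,

over the training positive set y and negative set ȳ (all never-positive
pairs by default; no negative sampling).  The score-space form clamps
scores to [1e-12, 1−1e-12] inside the logs.  Training itself evaluates
the identical objective from pre-activation logits through a stable
log-sigmoid: when initial logits saturate, scores underflow to exactly
0/1 in double precision and a clamped-log loss has zero gradient
everywhere, freezing training; the logit form's gradient (σ(x) − y)
never vanishes.  Both paths agree to machine precision away from
saturation and are cross-checked in the tests.

Optimization is full-batch Adam.  Edge dropout γ removes association
and protein edges independently per epoch *before* normalization
constants are computed; feature dropout β is applied to the fused
drug/disease embeddings after each layer (inverted dropout).  Dropout
placement is a recorded design choice — the source formulation names
the two rates without fixing placement.  No early stopping: training
runs for a fixed epoch count.

All tensor computation runs on a small reverse-mode autodiff engine
over dense float64 numpy arrays (`emphcn.autodiff`).  Softmax row-max
shifts are detached (exact for softmax), masked attention rows with no
neighbors yield exact zero rows, and gradient correctness is pinned by
central finite differences end-to-end (relative error ~1e-8 measured).

## Parameters

| name | default | meaning |
|------|---------|---------|
| k1, k2 | 256, 128 | hidden widths of the two layers |
| lr | 0.002 | Adam learning rate |
| beta | 0.4 | feature dropout on fused embeddings |
| gamma | 0.35 | edge dropout on association/protein graphs |
| epochs | 4500 | training epochs (fixed; no early stopping) |
| knn_k | 15 | hypergraph neighbors (clamped to Nv−1 with a warning) |
| eca_kernel | 3 | channel-attention convolution length (odd) |

Defaults follow the reference setting for the full-scale benchmark
datasets.  For simulated networks of a few dozen entities the package
uses `small_config()` (k1 = 64, k2 = 32, lr = 0.01, β = 0.1, γ = 0.1,
500 epochs) — widths and rates scaled to the entity counts, chosen
once as the small-problem setting.

## Synthetic data

`synthgen` plants a low-rank logistic structure: factors
U ∈ R^{M×r}, V ∈ R^{N×r} are standard normal; association
probabilities are `σ(UVᵀ + b)` with b calibrated by bisection (not a
closed form, so arbitrary rank/variance settings work) to hit the
target density within 1e-3; associations are independent Bernoulli
draws.  Every drug and disease is guaranteed at least one association:
empty rows are redrawn conditioned on a positive, then any still-empty
column receives its most probable entry.  Similarity views are
logistic transforms (gain 3) of the correlation kernel of the rows of
U with symmetric Gaussian noise per view, unit diagonal, clipped to
[0,1]; the disease similarity is the noise-free kernel of V.  Proteins
get unit latent directions; drug/disease–protein links are drawn with
probability increasing in factor–direction alignment (floored at
`protein_link_prob`), and PPI edges connect direction-similar proteins
with a nearest-direction fallback so no protein is isolated.  A seed
fully determines the output, byte for byte.

What this emulates: multiple noisy views consistent with one shared
drug latent structure, association sparsity, and protein links
correlated with the same factors.  What it does not: biologically
differentiated similarity semantics (target vs. pathway views differ
only statistically here), weighted PPI confidences, and the scale and
degree heterogeneity of curated databases.  Passing the synthetic
study therefore shows that the implementation recovers planted
latent-proximity structure above a popularity baseline — not that it
reproduces benchmark-level performance on real data.

Two intrinsic properties of this design bound held-out recovery.
First, Bernoulli sampling caps attainable ranking quality: even
scoring test pairs with the true planted probabilities leaves their
AUROC well below 1.  Second, a correlation-type kernel exposes only
within-domain *directions* of the latent factors (magnitudes and the
cross-domain rotation are only identifiable from the training
associations, which 2-fold splitting halves).  The acceptance script
reports the model's measured held-out AUROC next to the degree-product
baseline and the ablation variants so the margin over popularity and
the contribution of each enhancement are visible on equal terms.

## Numerical and protocol choices

* Similarity loading repairs asymmetry up to 1e-6 by symmetrization and
  rejects larger asymmetry as corruption; diagonals are forced to 1;
  values clipped into [0,1] with a warning beyond 1e-6.  Parsing uses
  round-trip float precision so load→write→load is bit-identical.
* Identifier ordering follows the first-loaded component per domain;
  later components are re-indexed to it.
* Entity filtering (e.g. minimum protein targets per drug) is a data-
  preparation concern; assembly only counts and reports such nodes.
* Cross-validation scores each fold's test positives against all
  never-positive pairs (training positives excluded from scoring).
  Leakage is asserted programmatically on every split.
* Thresholded metrics (recall/accuracy/F1) use 0.5 on the logistic
  scores; exposed as an argument since any published accuracy implies
  some threshold choice.
* AUPR is the step-wise non-interpolated precision–recall integral;
  the variant matters at extreme positive sparsity.
* The cold-start protocol holds out whole disease columns; repeats use
  independent random draws by default, with a disjoint-partition mode
  (`novel_disease_partition`) covering each disease exactly once.
* Ranking ties are broken by identifier order everywhere.

## Known limitations

* Full-batch dense training: fine up to a few thousand entities, not
  intended for genome-scale protein sets.
* Single-head attention; no edge attributes; unweighted PPI.
* The two-layer depth is fixed; the ablation toggles change routes,
  not depth.
* Hyperparameter search is out of scope; defaults are the reference
  setting and `small_config()` for simulations.
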