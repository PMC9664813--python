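# Methods

This note documents the model implemented in `bdhns`, the choices made
where the design was genuinely open, what the synthetic benchmark does and
does not show, and the package's known limitations.

## Model

The predictor treats microbe–disease association as link prediction on a
heterogeneous network with two node types. All quantities derive from a
binary association matrix A (diseases × microbes) and four kinds of side
annotation.

### Similarity channels

- **GIP kernels (GM, GD).** exp(−r‖x_i−x_j‖²) over association profiles
  (columns of A for microbes, rows for diseases), with the bandwidth
  normalized by the mean squared profile norm so the kernel adapts to
  association density. The bandwidth scale parameters default to 1. These
  are the only similarity channels that read A, and therefore the only
  ones refit per cross-validation fold.
- **Microbe functional similarity (FM).** Counts of shared (organ,
  disease) annotations — two microbes resident in the same organ and
  annotated to the same disease there score one unit — min–max normalized
  over the matrix. The raw diagonal is held at zero so the normalization
  spans the off-diagonal evidence; an all-equal count matrix normalizes to
  zeros (no evidence).
- **Disease semantic similarity (DSS).** Wang-style hierarchy similarity:
  each disease is its ancestor closure in a child→parent DAG, ancestors
  contribute Δ^depth with Δ = 0.5 (computed by reverse-topological dynamic
  programming, max over children), and similarity is shared contribution
  mass over the summed semantic values. Diseases absent from the hierarchy
  get identity rows (self 1, others 0) — a neutral fallback that keeps the
  four-channel average defined.
- **Disease functional similarity (DF).** Gene–gene log-likelihood scores
  min–max rescaled over the whole network (an all-equal network rescales
  to ones: a constant weight is still evidence of linkage); a gene matches
  itself at 1, a neighbor at its rescaled weight, any other gene at 0; a
  disease pair averages each gene's best match against the other set.
  Empty gene sets get identity rows.
- **Symptom similarity (TD).** Cosine of non-negative symptom profiles;
  an all-zero profile is defined dissimilar (0) to everything but itself.
- **Fusion.** SM = GM averaged with FM where FM has evidence, GM
  elsewhere. SD = (GD + DSS + TD + DF)/4.

### Bi-directional network and transition matrix

The cross correlations A′_SD = SD·A and A′_SM = A·SM weigh each known
association by the similarity mass behind it, giving direction-specific
cross edges rather than a single symmetric bipartite block. The adjacency
stacks [[SD, A′_SD], [A′_SMᵀ, SM]]. The transition matrix W gives every
associated node probability φ of jumping across types (distributed over
its associated partners proportionally to the cross correlations) and
1−φ of moving within its similarity network; unassociated nodes keep all
mass within type. Every row sums to one by construction; a zero similarity
row sum is rejected as an error. φ defaults to 0.5 (an uninformative
midpoint — the method's source material never fixes it), exposed in the
configuration.

### Restart walk

P(t+1) = (1−r)·Wᵀ·P(t) + r·P(0), iterated in column-stochastic
orientation so each column remains a probability distribution (the
defining conservation property of a walk). Defaults r = 0.1, t = 20, the
tuned operating point of the method; the fixed step count is the primary
stopping rule for reproducibility, with an optional early-stop tolerance
off by default. P(0) = I, so column j of P(t) is node j's diffusion
profile — its neighbor-topology features. A closed-form fixed point
(I − (1−r)Wᵀ)P = rP(0) serves as the test oracle.

### Selection scoring

Node attributes X default to the walk profile P(t) (the raw transition
matrix is available as `attributes: transition_matrix` and is what the
walk-disabled ablation uses). A parameter-free graph convolution
propagates attributes over the symmetrically normalized adjacency with
self-loops, once over the full network and once over its same-type-only
part (the causal intervention), then centers the features within each
node type and applies one shared seeded Gaussian projection to d = 64
dimensions. Pair scores blend the cosine-weighted association profiles of
both sides:

    ŷ(m(i), d(j)) = [Σ_k Sim(h_m(i), h_m(k))·A(j,k) + Σ_k Sim(h_d(j), h_d(k))·A(k,i)]
                    / [Σ_k Sim(h_m(i), h_m(k)) + Σ_k Sim(h_d(j), h_d(k))]

with Sim the cosine clamped to [0, 1] (zero vectors score 0), so ŷ stays
in [0, 1] and a zero denominator scores 0. The causal effect e = ŷ − ŷˢ
selects the reported score per pair: ŷ where e ≥ m (ties to the full
branch), ŷˢ otherwise, with m = 0 by default.

Two numerical design choices here deserve explanation, because the
aggregation is deliberately training-free (no weights, loss or
backpropagation — see Limitations):

- **Per-type centering.** Propagation over a dense similarity network
  drives every node's features toward the network's dominant diffusion
  component; without centering, all pairwise cosines saturate above 0.95
  and the score surface degenerates to node popularity. Subtracting each
  node type's mean feature vector removes exactly that shared component
  and restores discriminative cosines. Centering is per type because the
  intervened network keeps the two types in disjoint subspaces, where a
  global mean would leave each type a large type-specific offset.
- **One propagation layer.** The walk-profile attributes already encode
  t = 20 steps of diffusion; stacking further convolution layers
  re-smooths already-smooth features, measurably degrading cross-validated
  ranking. One layer suffices to mix each node's attributes with its
  neighborhood; depth is configurable (`gcn_layers`).

## Evaluation protocols

- **Leave-one-out.** Each known association is masked, the
  association-dependent quantities (GIP kernels, cross correlations, W,
  walk, embeddings, scores) are refit, and the held-out pair is pooled
  with that fold's scores for every pair unobserved in the full data. The
  pooled Mann–Whitney AUC (tie mid-ranks) is reported; a masked positive
  is never counted as a negative. FM, DSS, DF and TD never read A and are
  cached across folds.
- **Five-fold.** Positives are shuffled by seed into five groups; per
  fold, four groups train, one tests, and a without-replacement sample of
  negatives equal to the training positives is excluded from testing. The
  mean of per-fold AUCs is reported.
- **Ablations.** Walk-disabled feeds X = W to the convolution (no
  diffusion); selection-disabled reports the full-neighborhood ŷ only.

## Synthetic benchmark

The generator plants B = 3 blocks over 15 diseases × 60 microbes.
Associations are Bernoulli(p_in = 0.3) within blocks and
Bernoulli(p_out = 0.02) across. Every annotation channel correlates with
block membership, because the method's premise is that multi-source
similarity agrees with the association signal: each block owns one organ
(microbes annotated there with the block's diseases), one branch of a
two-level disease hierarchy under a shared root, one dense gene pool
(complete within-pool LLS edges, weights uniform on [1, 5]; 5% cross-pool
edges; each disease draws 4 genes, 80% from its own pool) and one band of
symptom dimensions (prototype plus Gaussian noise with sd 0.2, truncated
at zero). All draws flow from one seed; identical seeds give
byte-identical files.

What passing means — and does not. Within a block, planted edges are
i.i.d., so block membership is the only recoverable signal and the best
possible leave-one-out AUC at these settings is about 0.81–0.84 depending
on the realized draw (cross-block positives are unpredictable and
within-block negatives tie with true positives under any block-respecting
score). The pipeline's mean of ≈ 0.81 over seeds therefore indicates
near-ceiling recovery of the planted structure, not performance on real
association data, whose similarity channels are noisier, sparser and not
block-structured, and whose degree distributions are heavy-tailed. The
measured contribution of the walk enhancement is marginal at this ceiling;
the ablation ordering is directional, not a reproduction of any published
effect sizes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `microbe_bandwidth_scale`, `disease_bandwidth_scale` | 1.0 | GIP bandwidth numerators |
| `semantic_decay` | 0.5 | per-level attenuation Δ in DSS |
| `jump_phi` | 0.5 | cross-type jump probability in W |
| `restart_r` | 0.1 | walk restart probability |
| `walk_steps` | 20 | fixed walk iteration count |
| `gcn_layers` | 1 | propagation depth |
| `embed_dim` | 64 | projection dimension d |
| `projection_seed` | 13 | seed of the shared Gaussian projection |
| `select_threshold_m` | 0.0 | causal-effect selection threshold |
| `attributes` | `walk_profile` | node attribute source (`transition_matrix` for the literal X = W) |

## Limitations

- The graph convolution is an untrained propagation; no weights are
  learned, so published figures obtained with a trained aggregator are
  outside what this package reproduces or promises.
- The degenerate-case conventions (identity rows for unannotated
  diseases, zero cosine for zero vectors, min–max fallbacks) are
  conservative defaults, not estimates; heavily incomplete annotation
  degrades the affected channels toward the identity.
- Dense matrices throughout: the implementation targets databases of a
  few hundred nodes per type and makes no sparse-storage guarantees.
- The synthetic benchmark's block structure is far cleaner than real
  multi-source biology; results on it bound correctness, not field
  performance.
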