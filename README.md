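# bdhns

Microbe–disease association prediction on a bi-directional heterogeneous
network.

The human microbiome is implicated in a wide range of diseases, but
experimentally confirming which microbe is linked to which disease is slow
and expensive. `bdhns` ranks candidate (microbe, disease) pairs from a small
set of known associations plus side information — where microbes reside and
what they affect, how diseases relate in a hierarchy, which genes and
symptoms they share — so that laboratory follow-up can focus on the most
promising pairs. It is aimed at computational biologists doing network-based
link prediction on association databases such as HMDAD.

## Method

Given a binary association matrix **A** (n_d diseases × n_m microbes), the
pipeline has four stages:

1. **Similarity fusion.** Microbes: a Gaussian interaction profile (GIP)
   kernel GM(i,j) = exp(−r_m‖A(·,i)−A(·,j)‖²) with bandwidth r_m normalized
   by the mean squared profile norm, fused with an organ/disease
   co-annotation count FM into SM (mean of the two where FM has evidence,
   GM otherwise). Diseases: GIP (GD), hierarchy-based semantic similarity
   (DSS, ancestor contributions attenuated by Δ = 0.5 per level),
   gene-network functional similarity (DF, best-match log-likelihood
   scores), and symptom cosine similarity (TD), averaged into
   SD = (GD + DSS + TD + DF)/4.
2. **Bi-directional heterogeneous network.** Direction-specific cross
   correlations A′_SD = SD·A and A′_SM = A·SM weigh each association by the
   similarity topology on the other side. These blocks join SD and SM into
   the network adjacency A_all and a row-stochastic transition matrix W in
   which each associated node jumps across types with probability φ = 0.5.
3. **Restart random walk.** P(t+1) = (1−r)·Wᵀ·P(t) + r·P(0) with r = 0.1,
   t = 20 and P(0) = I gives every node a diffusion profile over the whole
   network — its neighbor-topology feature vector.
4. **Selection scoring.** Two parameter-free graph-convolution passes
   produce node embeddings: one over the full network and one with
   cross-type edges severed (the causal intervention). Each yields a score
   ŷ(m(i), d(j)) that blends the cosine-similarity-weighted association
   profiles of both sides. The causal effect e = ŷ − ŷˢ measures what the
   cross-type neighborhood contributed; per pair, the reported score is ŷ
   where e ≥ m (default m = 0) and ŷˢ otherwise.

Evaluation follows the standard link-prediction protocols: leave-one-out
(each known association masked and re-ranked against unobserved pairs) and
five-fold cross-validation over the positives, both scored by rank-based
AUC.

## Worked example

Everything runs on seeded synthetic data with planted block structure — no
downloads:

```python
from bdhns import BDHNSModel, SyntheticParams, generate_dataset, loocv

data = generate_dataset(SyntheticParams(seed=7))   # 15 x 60, 3 blocks
results = BDHNSModel(data.associations, data.annotations).fit()
print(results.summary())
print(results.top_predictions("d00", n=5).to_string(index=False))
cv = loocv(data.associations, data.annotations)
print(f"LOOCV AUC: {cv.auc:.4f}")
```

```
Bi-directional heterogeneous network association model
========================================================
Diseases: 15    Microbes: 60    Known associations: 102
Jump probability phi: 0.5    Restart r: 0.1    Walk steps: 20
GCN layers: 1    Embedding dim: 64    Selection threshold m: 0.0
Attributes: walk_profile
--------------------------------------------------------
Score range: [0.0000, 0.5750]    mean 0.1162
Full-neighborhood branch chosen for 74.7% of pairs
Mean |causal effect|: 0.0044
Walk residual after 20 steps: 8.12e-06

 rank microbe    score  known
    1     m05 0.294111  False
    2     m14 0.255590  False
    3     m13 0.254504  False
    4     m08 0.252643  False
    5     m19 0.251773  False

LOOCV AUC: 0.8170
```

The summary reports the network dimensions and operating point; the ranking
lists the highest-scoring microbes not already associated with disease
`d00` (all five here belong to `d00`'s planted block). The leave-one-out
AUC of 0.82 says a masked true association outranks a random unobserved
pair 82% of the time — against an information ceiling of roughly 0.81–0.84
on this generator, since within a block the planted edges are random.

The same pipeline is available from the shell:

```bash
bdhns simulate --seed 7 --out-dir data/
bdhns predict --associations data/associations.tsv \
              --annotations data/annotations.yaml --out pred.tsv
bdhns evaluate --associations data/associations.tsv \
               --annotations data/annotations.yaml --cv loocv
```

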