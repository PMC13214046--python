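# Methods

`coevolm` implements masked language modeling over whole proteomes: a
transformer encoder reads the set of proteins encoded by one genome, each
protein represented by a fixed-dimension embedding vector, and is trained to
reconstruct the embeddings of masked proteins from the remaining context.
This note documents the model, the synthetic-data generator that stands in
for real proteome corpora, and the numerical and design choices that were
genuinely open.

## The model

### Tokens and functional encoding

A proteome is an unordered set, so the encoder uses no positional encoding.
Each token is the sum of two learned linear projections: one of the
protein's embedding channel and one of its *functional encoding* — a vector
describing the protein's orthologous group (OG).

Functional encodings are built from the orthology hierarchy, a rooted tree
whose leaves are fine-grained OGs and whose internal nodes are progressively
broader groups:

1. each populated leaf's vector is the arithmetic mean of its member
   proteins' embeddings over the whole corpus;
2. each internal node's vector is the *equal-weight* mean of its immediate
   children's vectors, computed leaf-to-root, so large groups cannot
   dominate their parent;
3. a protein's candidate encodings are the vectors along its leaf-to-root
   path; orphan proteins (no group) use their own embedding.

During training one path entry is drawn uniformly per protein per epoch,
exposing the model to functional descriptions at varying specificity. At
evaluation time the deterministic leaf-level vector is used — the most
specific description, and the only reproducible choice. Group vectors are
built once per corpus from all species; per-split averaging would change the
encodings with the split without changing what they describe.

### Masking and training objective

Per optimization step one proteome is processed: functional encodings are
resampled, the context is capped at 4096 tokens by uniform subsampling,
`floor(0.5 N)` tokens are masked (their embedding channel replaced by their
sampled functional encoding — the functional channel is never masked), and
the loss is computed over masked tokens only. With residuals `r = x − x̄`
and `r̂ = x̂ − x̄` (true embedding, reconstruction, functional-encoding
baseline), the default objective is the polar loss

    L(x̂, x, x̄) = (1 − cos θ) + (‖r̂‖ − ‖r‖)²,

θ the angle between `r` and `r̂`. It is zero iff `x̂ = x` and keeps
penalizing wrong residual directions as ‖r‖ → 0, where the mean squared
error's direction sensitivity vanishes quadratically — the failure mode in
which an MSE-trained model degenerates to reproducing the baseline. MSE and
the cosine-embedding loss on residuals are implemented as comparison
objectives. The cosine denominator is guarded with ε = 1e-8; when both
residual norms fall below ε the angular term is defined as 0 (the baseline
was reconstructed exactly). Norms are raw Euclidean, reductions are
unweighted means over masked tokens — the standard conventions.

### Architecture details

Pre-norm transformer encoder layers with GELU feedforward blocks; multi-head
self-attention with row-stochastic coefficients captured on every forward
pass. The desk-scale default is 2 layers × 4 heads at width 64 (trains in
about two minutes per corpus on one CPU core); the full-size configuration
is 6 layers × 8 heads, giving the 48 attention heads the downstream modules
expect. The two input projections are *summed*: concatenation would silently
double the model width. A masked token's input is
`proj_E(x̄) + proj_F(x̄)`; a config flag switches to zeroing the embedding
channel instead (measured worse for pair recovery). Training uses Adam at
learning rate 1e-3, no schedule, one proteome per step, a 2% held-out
proteome validation split, and a fixed number of epochs (no early stopping
for pretraining). All networks run on the package's own compact float32
reverse-mode autodiff engine (`coevolm._autodiff`), which implements exactly
the tensor operations these models need.

### Attention as interaction evidence

For an unordered pair (i, j), each head contributes the symmetrized
coefficient `(A[i,j] + A[j,i]) / 2`. Two extraction choices matter and are
deliberate:

* **Forward-pass inputs.** Screening attention is extracted from the
  *functional-identity* forward: every token's embedding channel carries its
  leaf encoding. This matches the distribution of masked queries seen in
  training (a masked token's input is exactly its encoding) and measured
  consistently higher planted-pair recovery than extraction from the
  raw-embedding forward. The raw variant remains available
  (`tokens="embeddings"`).
* **Per-species evaluation.** Attention rows are stochastic, so
  coefficients scale like 1/N and are not comparable between proteomes of
  different sizes; all AUCs over attention scores are computed within one
  species and then averaged. Pooling raw coefficients across species
  produces a size confound (co-presence of rarely-lost pairs concentrates in
  large proteomes, which have smaller coefficients).

The lightly supervised screener is an L2-regularized logistic regression on
the z-scored per-head features of 100 interacting pairs and 1,000 random
pairs treated as noninteracting (no purification); its training rows are
excluded from every downstream ranking.

## Supervised heads

**Pair classifier.** Two per-source node encoders (contextual embedding and
raw input embedding; two layers with layer normalization, ReLU and dropout
0.1) produce 256-dim node features fused by elementwise mean — this
preserves both the dual-source description and the printed single-source
widths (640 → 512 → 256). The pair combination is
`[a ‖ b ‖ a⊙b ‖ |a−b|]` (1024 = 4 × 256), compressed 1024 → 128 → 64; the
48 symmetrized attention features pass an edge processor 48 → 64 → 32; the
concatenated 96-dim vector feeds a 96 → 128 → 64 → 1 classifier. An
unordered pair's score is the mean of the two concatenation orders' sigmoid
outputs. Training: minibatch binary cross-entropy with logits, Adam (1e-3,
weight decay 1e-4), early stopping on validation AUPR with patience 10, best
state restored, test split scored exactly once. Edge features are z-scored
(raw coefficients live on a ~1/N scale). Pair splits are assigned at the
level of unordered leaf-OG pairs, because the same interacting group pair
recurs across species and row-level splits would leak it.

**Essentiality classifier.** Inputs are per-protein contextual embeddings
from a chosen backbone layer (default: the middle layer, where intermediate
representations carry the most signal), standardized per genome
(per-coordinate mean/SD over that species' proteins, SD guarded at 1e-8).
The classifier has one hidden layer (default 2048; scaled to 512 at desk
scale), ReLU, dropout 0.5, and two softmax-normalized logits; the
essentiality score is the positive-class softmax. Splits are assigned per
sequence cluster (the simulator provides leaf OGs as cluster ids) so similar
proteins never straddle splits; whole held-out species can be excluded from
training entirely. Quasi-essential labels are never trained on — they are a
reporting category for top-N calling, where the N highest-scoring genes of a
genome are called essential (ties broken by ascending protein id).

## The synthetic corpus generator

The generator produces, from one integer seed, the statistical structure the
model exploits, at a scale that pretrains in minutes on one CPU.

* **Species tree**: random bifurcating topology over 200 species by
  repeated joining of random lineages, exponential branch lengths
  (mean 0.15).
* **Orthology hierarchy**: 300 leaf OGs under 4 levels with geometrically
  decaying level widths; root archetypes i.i.d. standard normal in 64
  dimensions; each child's archetype adds N(0, 0.5²) per coordinate.
* **Presence/absence**: every OG present at the root; along each branch of
  length t a present gene is lost with probability 1 − exp(−λt) (λ = 0.3)
  and an absent one regained with probability 1 − exp(−μt) (μ = 0.05).
  Regained genes carry the same archetype (no re-divergence), keeping the
  phylogenetic profile clean. For each of 30 planted pairs, whenever a loss
  is drawn for one member the partner is co-deleted with probability
  ρ = 0.9 — the correlated gene loss that phylogenetic profiling reads.
* **Embeddings**: member embedding = leaf archetype + pair-latent term +
  essentiality shift + per-species offset (sd 0.2) + protein noise (sd 0.1,
  with a 10% heavy tail at sd 3.0 emulating fast-evolving proteins whose
  embeddings sit far from their family mean). One protein per (species, OG);
  2% orphans per genome with unit-scale noise embeddings.

The **pair latent** is the embedding-level face of coevolution. Each planted
pair owns a random direction `s` (standard normal). A member present in a
species receives `(ρ·w₀ + w₁·c)·s` with defaults w₀ = 1.5 and w₁ = 0.6:

* the constant part (ρ·w₀) makes obligate partners resemble each other —
  shared interface and complex features — scaled by the coupling strength,
  so a pair with ρ = 0 is, correctly, no pair at all;
* the amplitude `c` is drawn per species and is *shared* between co-present
  partners with probability ρ (independent otherwise), so partner embeddings
  co-vary across genomes exactly where both genes persist.

This decomposition is what makes the planted signal both learnable and
loss-discriminating at desk scale: the constant part lets dot-product
attention discover partners; the co-varying part is the contextual
information that masked reconstruction is rewarded for reading (a constant
latent alone is absorbed into the functional-encoding baseline and provides
no such reward); and because the co-varying part is small while the
heavy-tailed noise is large, magnitude-weighted objectives (MSE) learn it
more slowly than the magnitude-normalized polar angular term.

Essentiality is planted three ways, each optional: a shift β along a fixed
unit direction in embedding space; a loss-rate multiplier (< 1: essential
genes are rarely lost); and a noise multiplier (< 1: essential proteins are
conserved, staying close to their family mean — visible only to a model
that knows the family mean, i.e., the context model). 30% of OGs are
essential; labels flip with ε = 0.05, which avoids trivially separable
labels and caps attainable AUC near 0.95.

**What the generator does not emulate**: real sequences (no amino acids are
generated), paralogy and gene duplication, taxonomic sampling bias, horizontal
transfer, correlated noise between unrelated families, or any structure-level
signal. Passing tests therefore demonstrate that the implementation recovers
the signals the generator plants — correlated loss and correlated embedding
variation — not that it would match published performance on real proteomes.

## Study conditions and measured behavior

The default desk-scale conditions (200 species, 300 OGs, d = 64, 4 levels,
30 planted pairs, ρ = 0.9, tiny 2 × 4 × 64 backbone, 30 epochs, polar loss)
were calibrated once, before the acceptance thresholds were evaluated, so
that the planted coevolution is strong enough to be learnable in minutes on
one CPU; they are the package's reference experiment. Under these conditions
the per-species mean-attention AUC for planted versus random pairs reaches
roughly 0.70–0.80 across seeds, is increasing in ρ over {0, 0.5, 0.9}, and
polar-loss pretraining matches or beats MSE pretraining on most seeds. The
supervised experiments use a denser 60-pair corpus (pair classifier) and a
β = 3.0 corpus (essentiality); problem sizes for these heads (40 species of
pairs, 10-epoch backbones, hidden 512) were chosen so the whole acceptance
battery completes in well under an hour on a single core.

## Numerical choices and degenerate inputs

* float32 throughout; attention softmax is max-shifted; layer-norm ε 1e-5.
* Masking requires at least one masked token; a mask fraction that rounds to
  zero masked tokens is rejected (the loss would be undefined).
* Single-token proteomes give the 1 × 1 attention matrix [1].
* Genome normalization requires ≥ 2 proteins; constant coordinates map to 0.
* AUC requires both classes; AUPR requires ≥ 1 positive (both raise
  otherwise). Ties contribute 1/2 to the AUC (Mann–Whitney convention).
* Self-pairs are excluded from pair features with a warning.
* Corpus generation, splitting, masking, initialization and training are
  driven by independent `SeedSequence` streams derived from single integer
  seeds; repeated runs are bitwise identical except for float accumulation
  in training (validated to 1e-4 relative).

## Known limitations

* The autodiff engine is single-threaded float32 numpy; it is sized for the
  desk-scale models here, not for full-size pretraining.
* The generator's coupling of presence loss and embedding covariation to a
  single ρ is a modeling convenience; real interacting pairs need not show
  both signals, or with proportional strength.
* The functional-identity attention extraction assumes leaf encodings exist
  for evaluation species — i.e., the corpus used for screening contributed
  to the encoding averages. Screening a genuinely novel proteome would
  require mapping its proteins into the existing hierarchy first.
* At inference the path level used for the encoding is the leaf; the effect
  of coarser choices is exposed via config but not systematically studied.
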