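# Methods

## Problem and model

`dtafusion` predicts the binding affinity `A = F_theta(P, D)` of a small
molecule `D` against a protein target `P` as a continuous regression target
(pKd for dissociation constants, `pKd = -log10(Kd / 1e9)` with Kd in nM, or a
composite KIBA score). The model is an early-fusion graph network:

1. **Drug, attention path.** Heavy atoms are nodes carrying a 9-slot integer
   feature vector (molecule size, chirality, degree, formal charge, attached
   hydrogens, radical electrons, hybridization, aromaticity, ring flag), each
   slot embedded and summed. Three structural encodings make the encoder
   graph-aware: learnable degree embeddings added to node features, one
   learnable scalar logit bias per shortest-path-distance bucket, and a
   bond-feature projection averaged along the canonical shortest path of each
   atom pair. The encoder is a sandwich of three top-S sparse self-attention
   layers (S = 25 by default; queries ranked by the exact max-minus-mean
   attention-logit score; unselected queries emit the mean value vector) with
   identity residual skips, interleaved with two distillation blocks (width-3
   convolution, ELU, stride-2 max pooling that halves the node axis; bias
   matrices are subsampled to the surviving — even — node indices). A final
   max pool gives the global drug feature.
2. **Drug, GCN path.** A separate feature slate (element, degree, position
   index, attached-H count as an implicit-valence proxy, charge,
   hybridization) feeds GCN layers with the symmetric normalisation
   `D~^{-1/2}(A + I)D~^{-1/2}`, residual blocks, a column-wise max pool, and
   two affine layers, producing the drug super-node vector. This path is
   permutation invariant; the attention path is not (its convolution/pooling
   axis is the parser's atom order, which is deterministic per input).
3. **Protein graph.** Residue nodes concatenate a per-residue sequence
   embedding (behind a provider contract; any language-model embedder with a
   declared width can be plugged in), one-hot 8-state secondary structure,
   and relative solvent accessibility. Edges are contacts — sequence
   separation >= 2 and distance strictly below 8 Å, or contact probability
   strictly above 0.5 — plus backbone (i, i+1) edges so the chain stays
   connected for message passing. Absolute ASA in Å² is normalised by
   Tien/Wilke maximum-ASA constants at load.
4. **Early fusion.** The drug super node becomes row 0 of a heterograph whose
   other rows are the (width-projected) residue nodes; cross edges join the
   super node to every residue. GCN + residual refinement runs jointly, then
   a boolean mask separates drug and protein rows again.
5. **Head.** Drug side: the global attention feature is concatenated with a
   GCN pass over the masked one-node drug subgraph (an affine map, since the
   normalised adjacency of one node is 1). Protein side: GCN over the masked
   residue subgraph, global max pool, ReLU, affine. The concatenation passes
   a two-layer fully connected stack (dropout before each affine during
   training only) to one scalar.

Training minimises mean squared error with Adam. All randomness —
initialisation, batch order, dropout masks — derives from a single seed, so
runs are bit-reproducible.

## Readings taken where the dataflow was ambiguous

* Attention output uses the standard weighted sum over value vectors
  `sum_j alpha_ij (W_V h_j)`; an output built from the query's own value
  vector alone would ignore every other node and defeat the global-context
  purpose of the layer.
* The per-pair spatial weight is one learnable scalar per SPD bucket (a free
  parameter per pair would be unbounded across molecules).
* "The" shortest path for the edge-path encoding is made deterministic by the
  lexicographically-smallest-node-sequence tie-break; averaging over all
  shortest paths is the documented alternative. Unreachable pairs contribute
  a zero edge bias (the neutral additive element) but have a dedicated
  spatial bucket.
* The Pearson metric uses the standard covariance-over-standard-deviations
  definition; the concordance index counts prediction ties as 0.5.
* The masked drug subgraph is a single super node, so the head's drug-side
  GCN reduces to an affine transform; the feature-axis concatenation with
  the global drug feature is the only shape-consistent reading.
* Dropout is applied in the head only.
* Hydrogens are implicit: graph nodes are heavy atoms, with attached-H
  counts as a node feature.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| `d_model` | 32 | width of all graph features; desk-scale choice |
| `hidden` | 256 | fully connected head width (declared set {256, 512}) |
| `top_s` | 25 | sparse-attention query budget; effective S = min(S, L) |
| `lr` | 0.001 | Adam (declared set {0.0005, 0.001, 0.01}) |
| `train_batch` | 64 | pairs per step |
| `dropout` | 0.2 | head only, training only |
| `gcn_blocks` / `res_blocks` | 2 / 2 | declared sets {1,2} / {2,3,4} |
| degree / SPD bucket caps | 16 / 20 | organic molecules rarely exceed these; one extra SPD bucket marks unreachable |
| contact cutoff | 8 Å strict, separation >= 2 | standard contact-map convention |
| `epochs` | 2000 | full-protocol default; every desk-scale run overrides it |

Out-of-set hyperparameter values are accepted with a warning rather than
rejected, so small-scale configurations remain expressible.

The split protocol shuffles pairs into six equal parts (±1), holds part 5
out as the independent test set and rotates parts 0–4 as 5-fold
cross-validation; a quadrant mode first cuts the pair list into four seeded
subsets, each split six ways (the KIBA-style setting). The split unit is the
(drug, protein) pair — a warm-start protocol; cold-drug/cold-target splits
are out of scope.

## Numerical engine

No GPU tensor framework is used: the package carries a compact reverse-mode
automatic-differentiation engine over NumPy arrays (`dtafusion.autodiff`)
providing exactly the operations the network needs (matmul, softmax,
ELU/ReLU, gather/scatter embeddings, width-3 convolution, strided max
pooling, concatenation, masked selection) plus Adam. Graphs here are tens of
nodes, so dense N×N attention and Floyd-Warshall-scale shortest-path work
are exact and cheap; the sparse-attention query score is computed exactly
rather than sub-sampled. Within a training batch each unique drug and
protein is encoded once and shared by its pairs; gradients accumulate
through the shared subgraphs. Static structure (molecular graphs, SPD
matrices, path-feature tensors, normalised adjacencies, protein node
features) is cached per entity across steps.

Degenerate inputs: a one-atom molecule passes through the attention stack as
a single node (S >= L selects it); an isolated node is safe in every GCN
because the added self-loop bounds the degree below by one; constant metric
inputs yield NaN correlation fields flagged `undefined` rather than silent
zeros; a loss that becomes non-finite aborts training with a diagnostic.

## Synthetic study data

The generator emulates the pipeline's inputs at desk scale:

* **Drugs** — ~50 drug-like SMILES templates with seeded halogen/methyl
  decoration of aromatic carbons, re-parsed for validity; <= 64 heavy atoms.
* **Proteins** — uniform random sequences of 24–48 residues; SS8 strings
  from a state-persistent Markov chain (self-transition 0.8, else uniform);
  relative ASA ~ Beta(2, 2); coordinates from a self-avoiding 3.8 Å-step
  random walk whose pairwise distances stand in for a Cβ distance map
  (measured contact density of non-adjacent pairs: ~0.1–0.3); Gaussian
  per-residue embeddings seeded by a sequence hash stand in for a language
  model, so the provider is deterministic with no download. The embedding
  provider and distance map are explicitly synthetic stand-ins: they
  reproduce shapes, ranges and determinism, not biological content.
* **Labels** — `2.0*heavy/64 + 1.5*rings/6 + 2.0*mean(ASA) + 3.0*helix +
  4.0*rings/6*helix + N(0, sigma)`, sigma = 0.1 by default. The interaction
  term makes the target irreducible to either branch alone, so held-out
  recovery exercises the fusion stage, not just one encoder. Label SD is
  ~0.9, so the noise floor (MSE 0.01) is well below the signal.

Passing these tests shows the implementation learns a planted
structure-dependent signal end to end; it does not show benchmark-level
accuracy on real kinase panels, which needs the external datasets,
pretrained residue embeddings and predicted contact maps, and
GPU-scale training.

## Desk-scale study conditions

Two training studies back the acceptance properties, both on 1 CPU:

* **capacity** — 50 pairs (10 drugs × 5 proteins), sigma 0.1, 300 epochs at
  lr 0.001: train MSE reaches the 0.05 region with train CI above 0.95;
* **recovery** — 400 pairs (20 drugs × 20 proteins), sigma 0.1, 120 epochs
  at lr 0.001 (the package's small-scale schedule): held-out Pearson and CI
  far exceed the 0.7 / 0.75 sanity thresholds.

Stochastic checks are asserted by majority over seeds {1, 2, 3}. The
encoding ablation is a one-sided direction check: disabling all three
structural encodings must not improve held-out MSE beyond two pooled
standard errors of the seed means. On a planted-descriptor target this
margin is intentionally conservative — the synthetic labels do not depend
on molecular topology as richly as real affinities, so the encodings'
positive contribution is not expected to reach significance here, only to
not be harmful.

## Known limitations

* The attention encoder's distillation stage is atom-order sensitive; order
  is deterministic per input but not canonicalised across SMILES variants of
  the same molecule.
* The drug enters fusion only as a super node; atom-level drug nodes in the
  heterograph (and learned per-residue cross-edge weights) are extension
  hooks, not implemented.
* No conformers, tautomers or salt handling beyond the parser; no
  uncertainty estimates; single attention head.
* The "position index" atom feature in the GCN path is kept for parity with
  the architecture but is non-transferable across molecules; it is clipped
  at the dictionary bound and neutralised in permutation-invariance tests.
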