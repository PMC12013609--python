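# Methods

`gatfp` predicts molecular fingerprints of metabolites from MS/MS
fragmentation trees and identifies compounds by ranking library
candidates against the predicted fingerprint. This note documents the
model, the numerical choices, and what the synthetic test bed does and
does not establish.

## Pipeline

1. **Trees → graphs** (`msio`, `graph_builder`). A fragmentation tree
   (fragments = nodes, neutral losses = directed parent→child edges) is
   read from SIRIUS-style JSON. Relative intensities are divided by the
   tree maximum, so every tree has max intensity exactly 1. Node
   features concatenate a per-element count one-hot (alphabet
   C,H,N,O,P,S,F,Cl,Br,I by default; counts capped at `max_count`, cap
   index absorbs overflow), m/z divided by 1000 Da (so it stays O(1)
   next to the one-hots), and relative intensity.
2. **Edge features**. Each structural edge carries a 2-vector
   `[PMI(i,j), TF-IDF(child)]` computed over the corpus of tree edges:
   `PMI(i,j) = ln( (#W(i,j)/#W) / ((#W(i)/#W)(#W(j)/#W)) )` with `#W`
   the corpus edge total, and `TF-IDF = rel_intensity * ln(S/F_j)` with
   `S` samples and `F_j` the document frequency of the child fragment.
   Natural log throughout (base is a parameter; only the scale changes).
3. **Encoder** (`gat_model`). A stack of multi-head graph-attention
   layers; per head, `alpha_ij = softmax_j LeakyReLU(a^T [Wh_i || Wh_j || e_ij])`
   with self-loops added to every node, heads concatenated (default
   3 layers x 4 heads x 256 = 1024-wide output), ReLU between layers,
   max-pool readout over nodes, a 2-layer linear head, sigmoid output.
   Trained with binary cross-entropy and AdamW (lr 1e-4, weight decay
   1e-4, batches of 64 graphs) under ten-fold cross-validation.
4. **Fingerprints** (`fingerprints`). The target concatenates nine
   families in fixed order (FP2 1024, AtomPair 2048, Avalon 512, MACCS
   166, Morgan 2048, RDKitFP 2048, CDK 1024, PubChem 881, Klekota–Roth
   4860 = 14 611 bits).
5. **Identification** (`library_query`). Candidates are retrieved by
   precursor-mass ppm window (denominator = query mass) or by canonical
   molecular-formula equality, then ranked by the bit-count cosine
   `c / sqrt(ab)` between the binarized (threshold 0.5) prediction and
   each candidate fingerprint. Ties break by candidate id.

## Design choices where the design was open

- **Edge features in attention.** The attention logit concatenates the
  edge feature vector after the two endpoint projections. An ablation
  flag (`use_edge_features=False`) removes it; replacing the features by
  all-ones at graph building (`edge_mode="ones"`) reproduces the
  connectivity-only (FFe) variant.
- **Direction.** Losses point parent→child; reverse edges are added by
  default so information can also flow toward the root. Self-loops carry
  zero edge features.
- **Dropout** (rate 0.5 by default) applies to layer inputs and to
  attention coefficients during training; `dropout_on` restricts it to
  one of the two sites.
- **Negative PMI** is kept (not clamped): edges come from tree topology,
  not from a thresholded association graph, so a negative association is
  information, not noise. A flag clamps at zero if wanted.
- **Fold transfer.** Vocabulary and corpus statistics can be fitted on
  training folds only; unseen test fragments map to a reserved UNK index
  with document frequency 1, and an edge whose formula pair was never
  counted gets PMI 0 (`missing_pair="zero"`), i.e. assumed independence.
  The command-line `build-dataset` stage fits statistics once on the
  corpus it is given; the benchmark protocol fits on the training split.
- **Fingerprint backends.** Only RDKit is available here. AtomPair,
  Avalon, MACCS (emitted as 166 bits by dropping the unused bit 0 of the
  167-bit convention), Morgan and RDKitFP are native; FP2 (linear-path
  hashed), CDK (path hashed, depth 8), PubChem (FCFP-like, folded to
  881) and Klekota–Roth (Morgan radius 3 folded to 4860) are surrogates
  that preserve each family's exact bit length and are labelled
  `rdkit-surrogate:*` in the config. Count-based families are binarized.
- **Numerical engine.** No deep-learning framework ships in the target
  environment, so the encoder runs on a small numpy reverse-mode
  autodiff engine (`autodiff`). Correctness is enforced by
  finite-difference tests for every primitive and by a dense brute-force
  attention oracle. BCE is evaluated from logits via the softplus
  identity for stability; the sigmoid output path is exact.

## Synthetic test bed

`synthetic_data.generate_corpus` plants a known fragment↔bit mapping:
each of 32 bits (prevalence 0.2) owns 2 dedicated fragments from an
80-formula CHNO pool; active bits emit their fragments with probability
0.9; every unassociated pool fragment intrudes with probability 0.1;
fragments are wired into a random rooted tree ordered by decreasing
mass, intensities are uniform and max-normalized. Associations are
disjoint by construction so the mapping is identifiable — a failure to
learn indicts the model, not the world. The paired candidate library
holds the true compound (fingerprint = target), formula-matched decoys
with 30% of bits flipped, and mass-shifted decoys beyond the widest
(100 ppm) window.

What the generator does **not** emulate: fragmentation chemistry,
isotope patterns, shared substructures between fingerprint bits,
instrument-dependent intensity noise, or real fingerprint bit
correlations. A green learnability test therefore establishes that the
pipeline recovers a recoverable signal end to end — not that it matches
published accuracy on real spectra.

## Scaled benchmark protocol

The published setting (≈47k trees, 3×(4×256) encoder, 300 epochs) is
far beyond a single-CPU test budget. `benchmarks` fixes a scaled
protocol: the stated synthetic world (400 samples, 32 bits) with a
one-layer, 2-heads × 64 encoder, dropout 0.3, AdamW lr 3e-3 / wd 1e-3,
200 epochs, last 10% held out. At this data scale deeper stacks
memorize the 360 training trees (train AUC 1.0, held-out ≈0.83) while
one attention layer generalizes (held-out ≈0.91–0.93 across seeds) —
the opposite of the large-corpus behaviour, where more layers were
needed; both observations are consistent with capacity/data balance.
The paper-scale 1024-wide architecture is exercised by shape checks
rather than training.

On this protocol the edge-feature ablation (connectivity-only FFe vs
full PMI/TF-IDF edges) shows a small ordering in favour of full edge
features on the 5-seed mean. The effect is much weaker than on real
data because the planted world carries most of its signal in node
identity; the test establishes direction, not magnitude.

## Known limitations

- Surrogate fingerprint families share bit lengths and general character
  with the originals but not bit semantics; cross-tool comparisons of
  individual bits are meaningless.
- The ppm convention divides by the query mass; at ≤100 ppm the
  difference from the candidate-mass convention is below 1e-4 relative.
- An all-zero binarized prediction scores 0 against every candidate (a
  warning is logged).
- Micro-averaging over all (sample, bit) pairs is used for every
  reported metric; per-bit (macro) metrics are not implemented.
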