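# gatfp

Molecular-fingerprint prediction from MS/MS fragmentation trees with a
graph attention network, and compound identification by fingerprint
similarity against a candidate library.

## The problem

Identifying metabolites from tandem mass spectra is the bottleneck of
metabolomics: spectral libraries cover a small fraction of chemical
space, so a spectrum must instead be mapped to *structural* information
that can be matched against large compound databases. This package
implements that route via fragmentation trees: fragments (with formula,
m/z, relative abundance) are the nodes, neutral losses the edges, and a
graph neural network predicts the compound's molecular fingerprint — a
binary vector whose bits mark substructure presence. The predicted
fingerprint is then scored against the fingerprints of database
candidates retrieved by precursor mass or molecular formula.

## The model

A fragmentation tree becomes an attributed graph:

- **node features** — per-element count one-hots of the fragment formula,
  scaled m/z, relative intensity;
- **edge features** — a 2-vector `[PMI(i,j), TF-IDF_ij]` borrowed from
  text-graph construction: pointwise mutual information of the two
  fragment formulas over all corpus edges,
  `PMI(i,j) = ln( p(i,j) / (p(i) p(j)) )` with `p` estimated from edge
  counts, and `TF-IDF_ij = rel_intensity × ln(S / F_j)` with `S` samples
  and `F_j` the number of samples containing fragment `j`.

The encoder is a multi-head graph attention network. For head `k` with
projection `W_k` and attention vector `a_k`,

    α_ij = softmax_j LeakyReLU( a_kᵀ [W_k h_i ‖ W_k h_j ‖ e_ij] ),
    h'_i = σ( Σ_j α_ij W_k h_j ),

heads concatenated (default 3 layers × 4 heads × 256 → 1024-wide),
max-pool readout over nodes, a 2-layer linear head and a sigmoid giving
per-bit probabilities in (0,1). Training: binary cross-entropy, AdamW
(lr 1e-4, weight decay 1e-4), batches of 64 graphs, ten-fold
cross-validation. The target concatenates nine fingerprint families
(FP2 1024, AtomPair 2048, Avalon 512, MACCS 166, Morgan 2048, RDKitFP
2048, CDK 1024, PubChem 881, Klekota–Roth 4860 = 14 611 bits).

Identification scores a binarized prediction against each candidate by
the bit-count cosine `c/√(ab)` and reports top-1/5/10 rates.

The encoder runs on a small numpy reverse-mode autodiff engine shipped
in the package (no deep-learning framework required); gradients are
verified against finite differences in the test suite.

## Worked example

Everything runs on a seeded synthetic corpus with planted
fragment↔bit associations (no downloads needed):

```
gatfp simulate --seed 7 --n-samples 60 --n-bits 16 --out corpus/
gatfp build-dataset --corpus corpus/ --out dataset/
gatfp train --dataset dataset/ --out run/ --epochs 20 --folds 3 \
      --layers 1 --heads 2 --head-dim 32
gatfp query --checkpoint run/fold0.npz --dataset dataset/ \
      --corpus corpus/ --out q/ --mode formula
```

Or, end to end from Python, the scaled benchmark protocol:

```python
from gatfp.benchmarks import heldout_auc
print(heldout_auc(seed=0, epochs=200))   # 0.9128
```

which trains a one-layer 2×64 attention encoder on 360 planted samples
and reports micro ROC AUC over all (held-out sample, bit) pairs — 0.91
means the planted fragment→bit signal is recovered almost to the
ceiling set by the generator's emission noise. The same model with
label-shuffled targets scores ≈0.47 (chance).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline quantities from scratch at the given
seed: it generates the planted corpus, fits vocabulary and corpus
statistics on the training split, trains the scaled encoder, evaluates
held-out fingerprint prediction, and runs formula-mode identification
with cosine ranking. With `--seed 1` it prints

```
held-out micro ROC AUC: 0.9334  PR AUC: 0.7899
formula-mode top-1/5/10: 0.425/0.675/0.675 (random top-1 0.004)
```

— the true compound ranks first in 42.5% of held-out queries against
formula-matched decoy sets where random guessing would manage 0.4%.

## Layout

| module | role |
|---|---|
| `gatfp.msio` | SIRIUS-style tree JSON, MassBank records, candidate TSV |
| `gatfp.graph_builder` | vocabulary, PMI/TF-IDF corpus statistics, graph assembly |
| `gatfp.fingerprints` | nine-family concatenated fingerprints (RDKit) |
| `gatfp.autodiff` / `gatfp.gat_model` | numpy autodiff, GAT encoder, training |
| `gatfp.evaluation` | micro-averaged ROC/PR, accuracy, F1 |
| `gatfp.library_query` | ppm/formula retrieval, cosine ranking, top-k |
| `gatfp.synthetic_data` | planted corpora and the hand-checkable toy fixture |
| `gatfp.benchmarks` | the scaled desk-scale protocol shared by tests and script |
| `gatfp.cli` / `gatfp.pipeline` | `gatfp` command-line workflow |

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
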