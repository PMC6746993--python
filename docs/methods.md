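# Methods

## Problem and model

Ribosomally synthesized and post-translationally modified peptides (RiPPs)
derive from short, gene-encoded precursor peptides (PPs) that are easy to
miss in genome annotation. `rippnet` frames precursor recognition as binary
sequence classification: given only a 20–120 aa amino-acid sequence, score
the probability that it is a precursor peptide, independent of RiPP class
and of the surrounding genetic context.

Each validated sequence is encoded as a 20 × 120 one-hot matrix: rows are
the canonical amino acids in the fixed alphabetical order
`ACDEFGHIKLMNPQRSTVWY`, columns are residue positions. Sequences longer
than 120 residues are truncated after position 120; shorter ones are
zero-padded on the C-terminal side, so residue *j* always occupies column
*j*. The alphabet ordering and the padding side are artifact conventions;
both are serialized with trained weights, so any trained model is
self-describing.

Five architectures consume this input, all ending in a 0.5-rate dropout
layer and a 2-unit softmax classification head (the two outputs are
non-negative and sum to 1, read as P(non-precursor), P(precursor)):

| name | trunk |
|---|---|
| `lstm` | bidirectional LSTM, 60 cells, 0.15 recurrent dropout → dense(60, ReLU) |
| `cnn_linear` | conv(64,k7) → conv(128,k5) → conv(64,k3) → maxpool(2) → dense(40, ReLU) |
| `cnn_parallel` | 3 branches, each conv(64,k)→maxpool(2)→conv(64,k) for k ∈ {3,6,9}, concatenated → conv(150,k3) → maxpool(3) → dense(60, ReLU) |
| `cnn_linear_lstm` | linear-CNN trunk with a 60-cell LSTM before the dense layer |
| `cnn_parallel_lstm` | parallel-CNN trunk with a 60-cell LSTM before the dense layer |

Convolutions are stride-1 with "same" zero padding and ReLU activations, so
stacked convolutions and pooling never underflow the 120-column input. The
linear-CNN filter/kernel sizes (64,128,64 / 7,5,3) and the parallel branch
kernels (3,6,9 with 64 filters per branch convolution) are package defaults
exposed in `ModelSpec` and stored in the model metadata; the architecture
family fixes only their count and arrangement. The "0.15 dropout" on the
bidirectional LSTM is implemented as variational recurrent dropout (one
mask shared across positions, applied to the hidden state entering the
recurrent matmul); it is configurable. Dropout of every kind is disabled at
inference, making prediction deterministic and batching-invariant.

The networks are built on a small reverse-mode automatic-differentiation
engine over numpy (`rippnet.nn`): broadcasting add/mul, matmul, the
pointwise nonlinearities, im2col-based 1-D convolution, non-overlapping max
pooling, concatenation, inverted dropout, and a fused softmax
cross-entropy. All parameters are float64; gradients of every primitive are
verified against central differences in the development process. Weight
initialization is Glorot-uniform (LSTM forget-gate bias 1), seeded from the
run seed.

## Training procedure

Curated precursor corpora are heavily imbalanced (≈7 negatives per
positive; the reference corpus has 2,726 positives and 19,224 negatives).
The loop handles this by subsampling rather than class weighting:

1. Every `resample_interval` rounds (default 5, starting at round 1), draw
   a fresh uniform 35% subsample of the negative pool (size ⌊0.35·n⌋;
   ⌊0.35·19224⌋ + 2726 = 9,454 sequences per cycle at corpus scale) and
   combine it with the full positive set.
2. Split that cycle set 85/15, stratified by class to within one record per
   class, into a training and a held-out partition. The split is redrawn
   whenever the subsample is redrawn.
3. Each round runs one epoch of Adam (lr 1e-3, batch 32) on sparse
   cross-entropy over the training partition, then measures total accuracy
   on the held-out partition.
4. Weights are checkpointed iff held-out accuracy strictly exceeds the best
   seen so far (ties do not refresh patience); the best value is retained
   across resamples.
5. Training stops after `patience` rounds (default 50) without improvement
   or at `max_rounds` (default 200). The checkpointed best weights — never
   the final-round weights — are returned, together with a per-round
   history (loss, held-out accuracy, checkpoint and resample flags, stop
   reason, and the best round's held-out partition for re-evaluation).

One "round" is one full epoch over the current training partition — the
smallest unit after which held-out accuracy can be measured and
checkpointed. A single `numpy` generator seeded from `TrainingConfig.seed`
drives subsampling, splitting, shuffling and dropout masks, so identical
(data, config, seed) reproduce the history byte-for-byte; the optimizer
state persists across resamples. Evaluation reports positive-set,
negative-set and total accuracy with their counts, because under 7:1
imbalance an all-negative classifier already reaches 19224/21950 ≈ 87.6%
total accuracy — the majority baseline every useful model must beat on the
positive class.

Calls use a 0.5 threshold on P(precursor), strict, with exact ties resolved
to non-precursor — the conservative choice for a discovery filter; the
threshold is exposed for precision/recall trade-offs.

## Synthetic benchmark

Real training corpora are assembled from external databases and mining
tools and are out of scope here; the generator (`rippnet.synthetic`)
reproduces the property that makes them learnable instead. Positives are
background-sampled sequences (uniform residue frequencies, lengths uniform
on [20, 120]) carrying a fixed 10-mer motif embedded at a leader-like
window (positions 3–12, mimicking the N-terminal recognition region
tailoring enzymes bind; a uniform-position mode exists) with per-position
substitution probability 0.1. Negatives are sampled from the positives'
empirical residue composition and rejected if any window reaches 60%
identity to the motif, so the classes match in composition to well under 2%
per residue and differ only in positional structure — a classifier cannot
succeed on amino-acid frequencies alone. Defaults for the benchmark runs:
300 positives with a 7:1 negative imbalance, matching the corpus imbalance.

Two oracles bound what is achievable: an exact sliding-window motif scan
separates the classes perfectly at zero substitution noise, and an exact
Bayes likelihood-ratio classifier under the generative model (motif window
versus background, equal priors) is the information-theoretic ceiling under
noise. Passing the benchmark shows the architectures learn positional
sequence signal under class imbalance; it does not show performance on real
precursor diversity (multiple motifs per class, class mixtures,
phylogenetic correlation, length–composition coupling), which only the real
corpora can test.

Hit-flag enrichment emulates the downstream genome-mining readout: external
binary annotations (in practice, profile-HMM hits to known precursor
families) are supplied per id, and fold enrichment is the hit rate among
precursor calls divided by the overall hit rate, reported as undefined (not
infinite) when a denominator is zero. In the acceptance script the flags
are simulated with 67% coverage of true positives and 0.02% of negatives,
the coverage structure typical of curated-family annotation.

## Numerical and design choices

* Records with non-canonical residues (X, B, Z, J, U, O, internal `*`) are
  excluded, never wildcard-substituted: the encoding has no 21st row. A
  single trailing `*` is stripped before validation since ORF callers emit
  it. Duplicate FASTA ids are an error (predictions are keyed by id).
* Length bounds [20, 120] are inclusive; `--allow-short`/
  `allow_out_of_range` waives them, in which case over-length sequences are
  truncated at encoding.
* Dereplication keeps the first occurrence of each exact sequence string
  (case-insensitive by construction: sequences are upper-cased on read).
* The negative subsample uses floor sizing; stratified split sizes are
  rounded with both partitions kept non-empty per class.
* A non-finite training loss aborts with the round index.
* Model persistence: an `.npz` weights file plus a JSON sidecar
  (format version, architecture, full hyperparameter spec, alphabet);
  loading rejects metadata with missing fields or a mismatched expected
  architecture. Save → load → predict agrees to 1e-6.

## Problem sizes

The shipped tests and the acceptance script run the benchmark at 300
positives / 2,100 negatives with the parallel CNN capped at 40 rounds
(patience 15), the per-architecture capacity checks at 60 + 60 noise-free
sequences (≤ 90 rounds, learning rate 3e-3), and the CLI reproducibility
checks at a few dozen sequences and ≤ 8 rounds — sizes chosen so the whole
suite completes in a few minutes on a single CPU while every loop property
(resampling cadence, strict checkpointing, both stopping rules) is still
exercised at full fidelity.

## Known limitations

* The engine is CPU/numpy only; training at real corpus scale (≈22k
  sequences, 200 rounds) is possible but slow compared to a GPU-backed
  framework.
* The synthetic benchmark's single shared motif is easier than real
  precursor diversity; reported benchmark accuracies are not estimates of
  accuracy on biological data.
* The pure-LSTM variants process all 120 columns including padding; very
  short sequences therefore carry long all-zero suffixes through the
  recurrence (the bidirectional variant mitigates this from the N-terminal
  side).
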