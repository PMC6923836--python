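# Methods

## Problem and encoding

Only the N-terminus carries sorting signals, so each protein is reduced to
its first 96 residues. A residue is one-hot encoded over the 20 standard
amino acids in the fixed alphabetical column order `ACDEFGHIKLMNPQRSTVWY`;
ambiguity letters (X, B, Z, U, O) become all-zero rows, and proteins shorter
than 96 residues are zero-padded. Targets are per-residue classes in the
fixed channel order (S, T, N). Padded positions are labelled N so every
target row is a valid one-hot vector and the 96-term loss sum is always well
defined; an optional mask (`TrainConfig.mask_padding`, off by default)
excludes padded positions from the loss instead. Column and channel orders
are frozen API contracts.

## Architecture

The network is a 1D U-Net parameterised by `NetworkConfig`:

| parameter | default | meaning |
|---|---|---|
| `m` | 24 (20 light) | channels at full resolution |
| `n` | 24 (20 light) | linear channel increment per pooling level |
| `depth` | 3 | pooling steps (96 → 48 → 24 → 12) |
| `kernel_size` | 3 | convolution width, odd so same-padding is symmetric |
| `convs_per_level` | 2 | convolutions per resolution level |
| `pooling` | average | `average` or `max` |
| `schedule` | linear | `linear` (m + l·n) or `doubling` (64·2^l) |

Convolutions are length-preserving (zero same-padding) so skip connections
concatenate without cropping and the output length equals the input length.
Up-sampling is a kernel-2 stride-2 transposed convolution followed by ReLU.
The final layer is a 1×1 convolution to 3 channels with per-position
softmax. Weight initialisation is He-uniform, seeded; there is no batch
normalisation or dropout.

The exact layer counts behind the published size ranges are not recoverable
from text, so the defaults here were chosen as the simplest symmetric
configuration whose closed-form weight count lands inside the published
ranges: `sigunet` (m=24, n=24, depth=3) has 184,443 trainable weights
(range 100,000–300,000) and `sigunet_light` (m=20, n=20, depth=3) has
128,423 (range 60,000–200,000). `count_parameters` computes the closed form
(`kernel·c_in·c_out + c_out` per convolution, `2·c_in·c_out + c_out` per
transposed convolution, `c_in·3 + 3` for the head) and is required to equal
exhaustive enumeration of the built model's arrays; the test suite sweeps
randomized configurations to hold the two routes equal.

The network is implemented directly in numpy with hand-derived backward
passes for every operator; gradients are verified against central-difference
numerical differentiation in the test suite (relative error ≤ 1e-4).

## Training

Adam (lr 1e-3, β = 0.9/0.999), batch size 64, minimising the mean over
proteins of the summed 96-term cross entropy. Probabilities are clipped to
[1e-7, 1] before the logarithm — numeric safety far below reportable
precision. Early stopping: training halts after `patience` (default 10)
epochs without validation-loss improvement, up to `max_epochs` (default
200), and the best-validation-epoch weights are restored. All randomness
(initialisation, shuffling) flows from a single integer seed; runs are
bit-reproducible at fixed thread count.

## Decision rule

The per-residue output is reduced to a protein-level call by: score = max
over all windows of 4 consecutive positions of the within-window minimum
S-probability; the protein is a signal peptide iff score > θ (strict). The
"probability of any four consecutive amino acids" statement is read as
*every residue in some 4-window individually exceeds θ* (min-over-window),
the stricter per-amino-acid reading; a window-mean statistic is available
(`DecisionConfig.statistic="mean"`) but min is the default. The window
length is exposed for ablation. Segmentation labels each position by argmax
with ties broken S > T > N (the channel order), and `sp_end` reports the
leading S-run length.

## Nested cross-validation

Outer k = 5 stratified folds (by protein-level class SP/TM/other, seeded
shuffle — homology-aware partitioning is out of scope since dataset
construction is). For each outer fold, the k−1 training partitions serve
directly as the inner folds: each hyper-parameter candidate
(architecture, threshold) is scored by the mean inner-validation MCC over
the k−1 inner splits, candidates sharing an architecture reuse the same
trained models (thresholds are decision-rule parameters), and ties break
toward fewer weights, then smaller threshold. The k−1 inner models of the
winning candidate are reused as the ensemble on the outer test partition —
their probability matrices are arithmetically averaged *before* the decision
rule — rather than retraining on the full outer training set; this follows
the literal "constructs k−1 models and their predictions are averaged"
protocol. The outer test ids are asserted disjoint from every inner
train/validation id set at run time.

## Synthetic data

The generator emulates the compositional grammar the method must learn:

* **sp** — `M` + n-region (1–5 residues; K/R with probability 0.6, else a
  neutral residue) + h-region (7–15 residues, uniform over A/I/L/F/V/W/M) +
  c-region (3–7 residues, uniform over S/T/G/N/Q with `A` forced at the −3
  and −1 positions before the cleavage site) + a mature region (30–150
  residues, uniform over all 20 amino acids). Labels are S through the
  cleavage site.
* **tm** — a hydrophobic helix of 15–25 residues labelled T, starting at a
  random position such that it ends within the first 70 positions, embedded
  in background sequence; no S labels.
* **other** — `M` + background, all N.

Region-length ranges follow the canonical description of signal-peptide
anatomy; residue compositions are the package's own choice (uniform draws
from fixed region alphabets, uniform background) — real proteomes have
non-uniform frequencies, organism-specific signatures and homology
structure, none of which is emulated. The (−3,−1) preference for small
residues is realised as a hard `A` at both positions. Mixed SP+TM
topologies are excluded. Passing the end-to-end tests therefore shows the
implementation can learn this grammar, not that it reaches benchmark
accuracy on curated UniProt-derived data.

## Problem sizes and numerical choices

The end-to-end recovery check trains `sigunet_light` on 2,000 synthetic
records (40 % SP / 30 % TM / 30 % other), with 200 of them held as the
validation split, and scores 500 held-out records at θ = 0.5, window 4. For
this clean, separable data the training schedule is shortened to
max_epochs 30 / patience 5 (the library defaults of 200/10 are sized for
noisier data); the run converges in ~20 epochs and reaches protein-level
MCC ≈ 1.0, FPR_TM below 1 %. Toy/oracle tests use smaller configurations
(m = n ≤ 8, depth ≤ 2) where numerical gradient checking is cheap.

Degenerate metric denominators (no predicted positives, no TM proteins) map
to 0 rather than NaN so reports are total. Max pooling breaks ties toward
the first element of the pair, making the backward pass deterministic.

## Known limitations

* No GPU or multi-threaded training; numpy BLAS only. Fine at desk scale
  (≈2 s/epoch for 2,000 proteins with the reduced model), slow beyond.
* Cleavage-site position accuracy is not scored; `sp_end` is reported but
  no (−3,−1) weight-matrix model is included.
* The published benchmark numbers on curated datasets are out of reach by
  construction: those datasets (UniProt + homology reduction) are not
  redistributable and their generation is explicitly out of scope.
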