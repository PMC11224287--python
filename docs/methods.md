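# Methods

## Problem and data model

An alternative-splicing event is a labeled tuple: two 140-nt DNA
windows (`seq_a`, `seq_b`, one per splice site of the event), three
positive integer length covariates (exon length, upstream and
downstream intron lengths, in nucleotides), an event category (ES,
Alt3, Alt5) and a binary label for high vs low inclusion level. The
two windows are treated as opaque paired inputs; the package does not
extract windows from genomic coordinates.

## Encoding

* One-hot channel order is fixed at A, C, G, T and documented because
  trained weights are not portable across orders.
* `N` encodes as an all-zero row (hard-masked base) rather than a
  0.25-uniform row; this preserves the {0, 1} entry invariant and the
  identity "matrix mass = 140 − #N".
* `U` is silently mapped to `T`; lowercase input is uppercased before
  validation.
* Length covariates are log10-transformed by default (raw lengths span
  2–5 orders of magnitude and would otherwise dominate the dense
  layer); the transform can be disabled per call
  (`featurize_lengths(..., log_transform=False)`).
* The on-disk format is a FASTA of windows (`<event_id>_A` /
  `<event_id>_B`) plus a UTF-8, tab-separated annotation table with a
  required header (`event_id`, `event_type`, `len_exon`,
  `len_intron_up`, `len_intron_down`, `label`).

## Architecture

Both variants are dual-branch 1-D CNNs over (length, channel) arrays.
Block order inside a branch is convolution → dropout → ReLU →
max-pool, exactly as listed in the reference layer table, even though
dropout before the activation is unusual; with ReLU the two orders are
functionally equivalent under inverted dropout (both scale and zero
the same coordinates), so the table's literal order is kept.

Defaults (eight-hidden-layer variant): filters (8, 16, 32, 64),
kernels (7, 4, 3, 2), pooling size = stride = 2, valid padding and
stride 1 in every convolution — forced by the published temporal
cascade 140 → 134 → 67 → … → 7. The merged head is
flatten(896) ⊕ lengths(3) → Dense(1024)+ReLU → Dropout(0.5) →
Dense(1)+sigmoid. Baseline variant: three blocks per branch, filters
(32, 8, 8), kernels (7, 4, 3), conv dropout 0.2.

Decisions on points the published description leaves open:

* The eight-layer variant's conv-block dropout rate is not printed; it
  defaults to 0.2, inherited from the baseline's stated rate.
* One prose passage describes the updated model with filters
  32/8/8/8 and a final kernel of 1, contradicting the layer table;
  the table (8/16/32/64, kernels 7/4/3/2) is authoritative here. The
  prose variant is expressible through `DSCConfig` if wanted.
* Dropout is standard inverted dropout (train-time scaling by
  1/(1 − rate), identity at inference).
* Weight initialisation is Glorot-uniform, seeded; biases start at 0.
* Binary cross-entropy uses the natural log; each log argument is
  clipped below at ε = 10⁻⁷, so an exactly correct prediction
  contributes exactly 0 and a hard wrong one a large finite value.

The engine (`splicecode.nn`) implements only what these topologies
need: valid-padding stride-1 Conv1D, inverted dropout, ReLU,
non-overlapping max-pooling (trailing remainder dropped, giving
15 → 7), dense layers, and Adam with bias-corrected moments. All
state is float32. An `ArchitectureError` names the first layer whose
kernel/pool cascade would drive the temporal dimension below 1.

## Training and evaluation protocol

10-fold cross-validation with a dedicated early-stopping fold:
samples are shuffled once (seeded) and dealt round-robin into ten
folds whose sizes differ by at most one. Rotation *r* tests on fold
*r*, early-stops on fold (*r* + 1) mod 10 (a deterministic rule; the
protocol only requires *some* designated fold) and trains on the
remaining eight. Every sample is tested exactly once; role sets are
asserted disjoint at run time.

The early-stopping "threshold" is realised as patience-based
monitoring of the early-stop fold's loss: training halts when the
loss has not improved by at least `min_delta` = 10⁻⁴ for
`patience` = 10 consecutive epochs, and the weights of the best
early-stop epoch are restored. Batch size defaults to 64 (not
specified by the protocol). One integer seed drives fold shuffling,
weight initialisation, batch order and dropout masks, and is recorded
in every report; identical seeds give bit-identical runs.

AUC-ROC is the Mann–Whitney probability with half credit for tied
pairs (computed via midranks), identical to trapezoidal integration
of the empirical ROC curve. A single-class test fold raises an error
naming the rotation instead of silently reporting 0.5. The epoch-sweep
harness runs the full cross-validation once per epoch budget for both
variants and tabulates the mean AUCs (budgets 10/50/100/150/200 by
default).

## Synthetic data generator

The generator emulates the structure of the human internal-exon
dataset, not its biology:

* **Event categories** are drawn with probabilities proportional to
  the real dataset's class sizes (4,952 ES : 1,388 Alt3 : 1,568 Alt5).
* **Sequences** are uniform i.i.d. background; with probability
  `signal_strength` (default 0.9) a high-inclusion event carries a
  donor-like 9-mer (consensus CAGGTAAGT) sampled from a PWM planted at
  offset 68 of window A and an acceptor-like 9-mer (TTTTNCAGG, N
  uniform) at the same offset of window B. PWM consensus weight is
  0.9 per position. Motifs in *both* windows mirror the premise that
  context at both splice sites determines inclusion.
* **Length covariates** are class-conditional log-normals centred on
  realistic scales (exon ≈ 140 nt, introns ≈ 1.5 knt, σ = 0.4/0.8 on
  the log scale) with a +0.15 log-mean shift for the positive class —
  weakly informative by design, so the third input contributes without
  trivialising the task.
* Labels are exactly balanced by construction; output is byte-identical
  for identical config + seed.

What passing tests on this generator show: the encoder, network,
gradients, optimizer, early stopping, fold bookkeeping and AUC
machinery recover a planted, position-fixed signal and report chance
when the signal is destroyed. What they do not show: performance on
real splicing data, whose signal is dispersed (branch points,
polypyrimidine tracts, ESE/ESS elements, positional variability) and
whose classes are unbalanced. The published headline AUCs (mean AUC
rising from ≈ 0.87 at 10 epochs to 0.92 at 200 for the eight-layer
variant, vs 0.85→0.91 for the baseline) require the original dataset
and are therefore not asserted anywhere in this package.

## Problem sizes used by the shipped checks

Architecture equivalence is checked on the freshly built default
model (no data). Signal recovery runs 2,000 events (n_per_class =
1,000, signal 0.9) for 10 epochs across all ten rotations, plus the
same under label permutation; the epoch-budget comparison runs 500
events at budgets (5, 10) for both variants. These sizes were chosen
as the smallest at which the stochastic properties are stable across
seeds.

## Known limitations

* The engine is CPU/numpy only and single-threaded apart from BLAS;
  it is meant for datasets of 10³–10⁴ events, not genome-scale
  training.
* Only size-=-stride max pooling is implemented (all published
  configurations use 2/2).
* `build_baseline` pins the baseline topology; non-topological
  hyperparameters are still taken from the supplied config.
* The per-event-type AUC breakdown is available by filtering records
  before `run_cv`; no stratified fold option is provided.
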