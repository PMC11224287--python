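# splicecode

Classification of alternative-splicing (AS) events in human internal
exons with a dual-branch 1-D convolutional network.

Most human multi-exon genes are alternatively spliced, and aberrant
splicing is implicated in cancers and other disease. Given an AS event
— exon skipping (ES), alternative 3′ acceptor (Alt3) or alternative 5′
donor (Alt5) usage — the task here is to predict whether the exon's
inclusion level is high or low from sequence alone: two 140-nt DNA
windows flanking the event's splice sites plus three length covariates
(the exon and its two neighbouring introns). The package is aimed at
computational biologists who want a reproducible, dependency-light
reference implementation of this classifier, its evaluation protocol,
and a synthetic data generator to exercise the whole pipeline.

## The model

Each window is one-hot encoded as a 140 × 4 matrix (channel order
A, C, G, T; N rows are all-zero). Two mirrored convolutional branches
process the two windows; each branch stacks four blocks of

> Conv1D (valid padding, stride 1) → Dropout → ReLU → MaxPool(2, 2)

with filters (8, 16, 32, 64) and kernels (7, 4, 3, 2), so the temporal
dimension shrinks 140 → 134 → 67 → 64 → 32 → 30 → 15 → 14 → 7. The
branch outputs are concatenated (7 × 128), flattened (896), joined
with the three log10-length features (899), passed through a
1,024-unit ReLU dense layer with dropout 0.5, and a single sigmoid
unit emits the inclusion probability ŷ ∈ (0, 1). Training minimises
the binary cross-entropy

L = −(1/N) Σᵢ [ yᵢ log ŷᵢ + (1 − yᵢ) log(1 − ŷᵢ) ]

with Adam (α = 5·10⁻⁴, β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸, no decay). A
six-hidden-layer predecessor (filters 32/8/8, kernels 7/4/3, dropout
0.2) is provided as the comparison baseline.

Evaluation is 10-fold cross-validation with a dedicated
early-stopping fold: rotation *r* trains on eight folds, monitors fold
(*r* + 1) mod 10 for early stopping and tests on fold *r*; the metric
is AUC-ROC (Mann–Whitney form, half credit for ties) averaged over
the ten rotations.

The network, its gradients and the Adam optimizer are implemented
directly on numpy; there is no deep-learning framework dependency,
and every run is exactly reproducible from a single seed.

## Worked example

```python
import splicecode as sc

# synthetic dataset: 2,000 events, donor/acceptor-like motifs planted
# in 90% of the high-inclusion class
records = sc.generate_dataset(sc.SyntheticConfig(
    n_per_class=1000, signal_strength=0.9, seed=11))

clf = sc.SpliceEventClassifier(records)          # eight-hidden-layer variant
report = clf.cross_validate(max_epochs=10, seed=11)
print(report.summary())
```

prints

```
Cross-validation report: dsc
  epoch budget : 10
  seed         : 11
  folds        : 10
  fold AUCs    : 0.9047, 0.9637, 0.9549, 0.9398, 0.9616, 0.9481, 0.9679, 0.9368, 0.9222, 0.9529
  mean AUC     : 0.9453
```

i.e. ten per-rotation test-fold AUCs and their mean: after ten epochs
the network separates motif-carrying from background events with a
mean AUC of 0.95, where 0.5 would be chance. Permuting the labels
(`sc.permute_labels`) drops the mean AUC to ≈ 0.49.

The same pipeline is scriptable from the shell:

```sh
splicecode simulate --n-per-class 1000 --seed 11 --out data/
splicecode summary  --model dsc                 # layer/parameter table
splicecode cv --data data/ --epochs 10 --seed 11 --out results/
splicecode cv --data data/ --sweep 5,10 --out sweep/   # both variants
```

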