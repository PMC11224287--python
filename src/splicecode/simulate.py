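"""Synthetic splice-event datasets with planted splice-site-like motifs.

The generator emulates the structure of a labeled human internal-exon
dataset: for every event two 140-nt windows, three length covariates
(exon, upstream intron, downstream intron) and a binary inclusion
label, spread over the three event categories (ES, Alt3, Alt5) in
proportions matching the relative sizes of the real dataset's classes
(4,952 ES : 1,388 Alt3 : 1,568 Alt5).

High-inclusion (positive) events carry a donor-like motif in window A
and an acceptor-like motif in window B, each sampled from a position
weight matrix planted at a fixed near-central offset with probability
``signal_strength``; everything else is uniform i.i.d. background.
Length covariates are class-conditional log-normals with a small shift
between classes, so the third input is weakly informative but does not
trivialise the task.  No attempt is made to model real splicing
grammar (branch points, polypyrimidine tracts) beyond these single
planted motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import BASES, SEQ_LEN, ANNOTATION_COLUMNS, SpliceEventRecord

__all__ = [
    "SyntheticConfig",
    "pwm_from_consensus",
    "DONOR_CONSENSUS",
    "ACCEPTOR_CONSENSUS",
    "generate_dataset",
    "permute_labels",
    "write_fixture",
]

#: 9-mer donor-site-like consensus (exonic CAG | intronic GTAAGT)
DONOR_CONSENSUS = "CAGGTAAGT"
#: 9-mer acceptor-site-like consensus (pyrimidine run, any base, CAG | exonic G)
ACCEPTOR_CONSENSUS = "TTTTNCAGG"

#: relative event-category sizes of the emulated dataset (ES, Alt3, Alt5)
_CLASS_WEIGHTS = np.array([4952.0, 1388.0, 1568.0])
DEFAULT_PROPORTIONS = tuple(_CLASS_WEIGHTS / _CLASS_WEIGHTS.sum())


def pwm_from_consensus(consensus: str, weight: float = 0.9) -> np.ndarray:
    """Position weight matrix concentrating ``weight`` on the consensus
    base per position; ``N`` positions are uniform."""
    if not 0.0 < weight <= 1.0:
        raise ValueError(f"consensus weight must lie in (0, 1]: {weight}")
    pwm = np.full((len(consensus), 4), 0.25)
    for i, base in enumerate(consensus.upper()):
        if base == "N":
            continue
        if base not in BASES:
            raise ValueError(f"consensus base {base!r} not in {BASES} or N")
        pwm[i] = (1.0 - weight) / 3.0
        pwm[i, BASES.index(base)] = weight
    return pwm


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``signal_strength`` is the probability that a positive event's
    windows carry a motif draw instead of pure background; 0 yields a
    label-free null dataset, 1 plants a motif in every positive.
    ``length_params`` maps each label to per-feature (mu, sigma) of a
    log-normal on the natural-log scale.
    """

    n_per_class: int = 1000
    event_type_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    pwm_a: np.ndarray = field(default_factory=lambda: pwm_from_consensus(DONOR_CONSENSUS))
    pwm_b: np.ndarray = field(default_factory=lambda: pwm_from_consensus(ACCEPTOR_CONSENSUS))
    motif_offset: int = 68
    signal_strength: float = 0.9
    length_params: dict = field(default_factory=lambda: {
        # (mu, sigma) per feature: exon, upstream intron, downstream intron
        0: ((4.94, 0.40), (7.31, 0.80), (7.31, 0.80)),
        1: ((5.09, 0.40), (7.46, 0.80), (7.46, 0.80)),
    })
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        props = np.asarray(self.event_type_proportions, dtype=float)
        if props.shape != (3,) or np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise ValueError(
                f"event_type_proportions must be 3 non-negative reals summing to 1: {props}")
        object.__setattr__(self, "event_type_proportions", tuple(props))
        for name in ("pwm_a", "pwm_b"):
            pwm = np.asarray(getattr(self, name), dtype=float)
            if pwm.ndim != 2 or pwm.shape[1] != 4 or np.any(pwm < 0) \
                    or not np.allclose(pwm.sum(axis=1), 1.0):
                raise ValueError(f"{name} rows must be probability vectors over ACGT")
            object.__setattr__(self, name, pwm)
            if self.motif_offset < 0 or self.motif_offset + pwm.shape[0] > SEQ_LEN:
                raise ValueError(
                    f"motif (width {pwm.shape[0]} at offset {self.motif_offset}) "
                    f"does not fit in a {SEQ_LEN}-nt window")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError(f"signal_strength must lie in [0, 1]: {self.signal_strength}")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _plant(rng: np.random.Generator, seq_idx: np.ndarray, pwm: np.ndarray,
           offset: int) -> None:
    for i, probs in enumerate(pwm):
        seq_idx[offset + i] = rng.choice(4, p=probs)


def _indices_to_seq(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def generate_dataset(config: SyntheticConfig | None = None, **overrides) -> list[SpliceEventRecord]:
    """Generate ``2 * n_per_class`` records with exactly balanced labels.

    Fully determined by ``config.seed``; keyword overrides are applied
    on top of the default configuration.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")

    rng = np.random.default_rng(config.seed)
    n_total = 2 * config.n_per_class
    # balanced by construction: first half positives, then shuffled
    labels = np.array([1] * config.n_per_class + [0] * config.n_per_class)
    labels = labels[rng.permutation(n_total)]
    event_types = rng.choice(3, size=n_total, p=config.event_type_proportions)

    records = []
    for i in range(n_total):
        label = int(labels[i])
        a = _random_seq(rng, SEQ_LEN)
        b = _random_seq(rng, SEQ_LEN)
        if label == 1 and rng.random() < config.signal_strength:
            _plant(rng, a, config.pwm_a, config.motif_offset)
            _plant(rng, b, config.pwm_b, config.motif_offset)
        mus_sigmas = config.length_params[label]
        lengths = tuple(
            max(1, int(round(rng.lognormal(mu, sigma))))
            for mu, sigma in mus_sigmas)
        records.append(SpliceEventRecord(
            event_id=f"ev{i:06d}",
            event_type=("ES", "Alt3", "Alt5")[event_types[i]],
            seq_a=_indices_to_seq(a),
            seq_b=_indices_to_seq(b),
            length_features=lengths,
            label=label,
        ))
    return records


def permute_labels(records, seed: int = 0) -> list[SpliceEventRecord]:
    """Return new records whose labels are a seeded permutation of the
    originals; sequences and features are untouched."""
    records = list(records)
    if not records:
        raise ValueError("cannot permute labels of an empty dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    return [
        SpliceEventRecord(
            event_id=r.event_id, event_type=r.event_type, seq_a=r.seq_a,
            seq_b=r.seq_b, length_features=r.length_features,
            label=records[perm[i]].label)
        for i, r in enumerate(records)
    ]


def write_fixture(records, out_dir) -> tuple[Path, Path]:
    """Write the FASTA + TSV pair that :func:`~splicecode.encoding.read_dataset`
    consumes; the round trip reproduces the records exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "sequences.fasta"
    tsv_path = out_dir / "annotations.tsv"

    with open(fasta_path, "w") as fa:
        for r in records:
            fa.write(f">{r.event_id}_A\n{r.seq_a}\n>{r.event_id}_B\n{r.seq_b}\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in records:
            le, lu, ld = r.length_features
            tsv.write(f"{r.event_id}\t{r.event_type}\t{le}\t{lu}\t{ld}\t{r.label}\n")
    return fasta_path, tsv_path
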