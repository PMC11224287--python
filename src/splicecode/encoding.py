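"""Splice-event records, one-hot sequence encoding and dataset I/O.

An alternative-splicing event is represented by two 140-nt DNA windows
(one per splice site of the event), three length covariates (the exon
and its two neighbouring introns, in nucleotides) and a binary
inclusion-level label.  Sequences become 140 x 4 one-hot matrices with
channel order A, C, G, T; unknown bases (N) become all-zero rows;
length features are log10-transformed by default.

Datasets live on disk as a FASTA file of sequence windows (two entries
per event, ids ``<event_id>_A`` / ``<event_id>_B``) plus a tab-separated
annotation table with columns ``event_id``, ``event_type``,
``len_exon``, ``len_intron_up``, ``len_intron_down``, ``label``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SEQ_LEN",
    "EVENT_TYPES",
    "ANNOTATION_COLUMNS",
    "SpliceEventRecord",
    "EncodedExample",
    "EncodingError",
    "one_hot_encode",
    "decode_one_hot",
    "featurize_lengths",
    "encode_record",
    "encode_dataset",
    "read_dataset",
]

SEQ_LEN = 140
#: channel order of the one-hot matrix; fixed because trained weights
#: are not portable across orders
BASES = "ACGT"
EVENT_TYPES = ("ES", "Alt3", "Alt5")
ANNOTATION_COLUMNS = ("event_id", "event_type", "len_exon", "len_intron_up",
                      "len_intron_down", "label")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_ALPHABET = set("ACGTNU")


class EncodingError(ValueError):
    """A record violates the sequence/length/label contract."""


@dataclass(frozen=True)
class SpliceEventRecord:
    """One labeled alternative-splicing event."""

    event_id: str
    event_type: str
    seq_a: str
    seq_b: str
    length_features: tuple[int, int, int]
    label: int

    def __post_init__(self):
        object.__setattr__(self, "seq_a", _clean_seq(self.seq_a, self.event_id, "seq_a"))
        object.__setattr__(self, "seq_b", _clean_seq(self.seq_b, self.event_id, "seq_b"))
        object.__setattr__(self, "length_features", tuple(int(v) for v in self.length_features))
        if self.event_type not in EVENT_TYPES:
            raise EncodingError(
                f"{self.event_id}: unknown event type {self.event_type!r} "
                f"(expected one of {EVENT_TYPES})")
        if len(self.length_features) != 3 or any(v < 1 for v in self.length_features):
            raise EncodingError(
                f"{self.event_id}: length features must be 3 positive integers, "
                f"got {self.length_features}")
        if self.label not in (0, 1):
            raise EncodingError(f"{self.event_id}: label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class EncodedExample:
    """Model-ready triple: two one-hot matrices, a 3-vector, a label."""

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    y: int


def _clean_seq(seq: str, event_id: str, which: str) -> str:
    s = str(seq).upper().replace("U", "T")
    if len(s) != SEQ_LEN:
        raise EncodingError(
            f"{event_id}/{which}: sequence length {len(s)} != {SEQ_LEN}")
    bad = set(s) - _ALPHABET
    if bad:
        raise EncodingError(
            f"{event_id}/{which}: characters outside ACGTNU: {sorted(bad)}")
    return s


def one_hot_encode(seq: str, *, event_id: str = "<seq>") -> np.ndarray:
    """Encode a 140-nt sequence as a 140 x 4 binary matrix (A, C, G, T).

    U is treated as T; N yields an all-zero row.  Each row therefore
    sums to 1 for a known base and 0 for an unknown one.
    """
    s = _clean_seq(seq, event_id, "seq")
    mat = np.zeros((SEQ_LEN, 4), dtype=np.float32)
    for i, base in enumerate(s):
        if base != "N":
            mat[i, _BASE_INDEX[base]] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` (all-zero rows decode to N)."""
    mat = np.asarray(mat)
    if mat.shape != (SEQ_LEN, 4):
        raise EncodingError(f"expected a {SEQ_LEN} x 4 matrix, got {mat.shape}")
    out = []
    for row in mat:
        out.append("N" if row.sum() == 0 else BASES[int(row.argmax())])
    return "".join(out)


def featurize_lengths(lengths, *, log_transform: bool = True) -> np.ndarray:
    """log10-transform the three length covariates.

    Raw exon/intron lengths span orders of magnitude; the log keeps the
    dense layer from being dominated by the longest intron.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.shape != (3,):
        raise EncodingError(f"expected exactly 3 length features, got shape {arr.shape}")
    if np.any(arr < 1):
        raise EncodingError(f"length features must be >= 1, got {arr.tolist()}")
    return np.log10(arr).astype(np.float32) if log_transform else arr.astype(np.float32)


def encode_record(record: SpliceEventRecord, *, log_transform: bool = True) -> EncodedExample:
    """Turn one record into the model-ready (140x4, 140x4, 3) triple."""
    return EncodedExample(
        x1=one_hot_encode(record.seq_a, event_id=record.event_id),
        x2=one_hot_encode(record.seq_b, event_id=record.event_id),
        x3=featurize_lengths(record.length_features, log_transform=log_transform),
        y=record.label,
    )


def encode_dataset(records, *, log_transform: bool = True):
    """Stack encoded records into (X1, X2, X3, y) arrays for training."""
    if not records:
        raise EncodingError("cannot encode an empty dataset")
    ex = [encode_record(r, log_transform=log_transform) for r in records]
    x1 = np.stack([e.x1 for e in ex])
    x2 = np.stack([e.x2 for e in ex])
    x3 = np.stack([e.x3 for e in ex])
    y = np.array([e.y for e in ex], dtype=np.float32)
    return x1, x2, x3, y


def read_dataset(sequences_path, annotations_path) -> list[SpliceEventRecord]:
    """Read a FASTA + TSV dataset into validated records, in table order.

    FASTA ids are ``<event_id>_A`` and ``<event_id>_B`` for the two
    windows of each event.  Rows referencing absent sequences, or
    duplicated ids in either file, raise :class:`EncodingError`.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(sequences_path), "fasta"):
        if rec.id in sequences:
            raise EncodingError(f"duplicate FASTA id {rec.id!r}")
        sequences[rec.id] = str(rec.seq)

    table = pd.read_csv(annotations_path, sep="\t", dtype={"event_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise EncodingError(f"annotation table missing columns: {sorted(missing)}")
    if table["event_id"].duplicated().any():
        dup = table.loc[table["event_id"].duplicated(), "event_id"].iloc[0]
        raise EncodingError(f"duplicate event_id in annotations: {dup!r}")

    records = []
    for row in table.itertuples(index=False):
        for suffix in ("_A", "_B"):
            if row.event_id + suffix not in sequences:
                raise EncodingError(
                    f"{row.event_id}: no FASTA entry {row.event_id + suffix!r}")
        records.append(SpliceEventRecord(
            event_id=row.event_id,
            event_type=row.event_type,
            seq_a=sequences[row.event_id + "_A"],
            seq_b=sequences[row.event_id + "_B"],
            length_features=(row.len_exon, row.len_intron_up, row.len_intron_down),
            label=int(row.label),
        ))
    return records
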