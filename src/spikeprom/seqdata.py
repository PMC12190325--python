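"""Sequence I/O, one-hot encoding, synthetic promoter generation, and fold assignment.

Promoter classifiers in this package consume fixed-length DNA sequences with
binary labels (1 = promoter).  Real benchmark sets come as one FASTA file per
class; the synthetic generator emulates their structure by stamping degenerate
consensus motifs (e.g. the prokaryotic -35/-10 boxes or the eukaryotic TATA
box) into random background sequence at characteristic offsets upstream of a
fixed transcription start site.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class ValidationError(ValueError):
    """Raised when an input violates a dataset contract."""


@dataclasses.dataclass
class SequenceRecord:
    """A labelled fixed-length DNA sequence."""

    id: str
    sequence: str
    label: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class Motif:
    """A degenerate consensus motif stamped at a fixed offset (0-based)."""

    consensus: str
    offset: int
    sub_prob: float = 0.15

    def __post_init__(self):
        if not all(c in _BASE_INDEX for c in self.consensus):
            raise ValidationError(f"motif consensus {self.consensus!r} has non-ACGT characters")
        if not 0.0 <= self.sub_prob <= 1.0:
            raise ValidationError(f"substitution probability {self.sub_prob} outside [0, 1]")
        if self.offset < 0:
            raise ValidationError(f"motif offset {self.offset} is negative")


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of a synthetic promoter dataset.

    Positives are background draws with every motif stamped at its offset and
    then corrupted per-position with probability ``sub_prob`` (uniform over the
    other three bases); negatives are pure background.
    """

    n_pos: int
    n_neg: int
    length: int
    motifs: Sequence[Motif]
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def validate(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ValidationError("background composition must be 4 nonnegative values summing to 1")
        if self.length <= 0:
            raise ValidationError("length must be positive")
        for m in self.motifs:
            if m.offset + len(m.consensus) > self.length:
                raise ValidationError(
                    f"motif {m.consensus!r} at offset {m.offset} overruns sequence of length {self.length}"
                )


# Canonical profiles.  The 81 bp prokaryote-style profile puts the TSS at
# position 60 (0-based) with TTGACA at -35 and TATAAT at -10; the 300 bp
# eukaryote-style profile puts the TSS at position 200 with a TATA box 30 bp
# upstream.  Both are configurable; these are defaults, not reconstructions of
# any particular species set.
def prok81_spec(n_pos: int, n_neg: int, seed: int = 0, sub_prob: float = 0.15) -> SyntheticSpec:
    return SyntheticSpec(
        n_pos=n_pos, n_neg=n_neg, length=81,
        motifs=[Motif("TTGACA", 60 - 35, sub_prob), Motif("TATAAT", 60 - 10, sub_prob)],
        seed=seed,
    )


def euk300_spec(n_pos: int, n_neg: int, seed: int = 0, sub_prob: float = 0.15) -> SyntheticSpec:
    return SyntheticSpec(
        n_pos=n_pos, n_neg=n_neg, length=300,
        motifs=[Motif("TATAAA", 200 - 30, sub_prob)],
        seed=seed,
    )


PROFILES = {"prok81": prok81_spec, "euk300": euk300_spec}


def _validate_sequence(seq: str, record_id: str, policy: str = "strict") -> str:
    seq = seq.upper()
    if policy == "strict":
        for pos, ch in enumerate(seq):
            if ch not in _BASE_INDEX:
                raise ValidationError(
                    f"record {record_id!r}: invalid character {ch!r} at position {pos}"
                )
    return seq


def read_fasta(path: str | Path, label: int, policy: str = "strict") -> list[SequenceRecord]:
    """Read one FASTA file, assigning every record the given class label.

    Sequences are uppercased and line wraps joined.  Under the default
    ``strict`` policy any character outside A/C/G/T raises
    :class:`ValidationError` naming the record and position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(str(rec.seq), rec.id, policy)
        records.append(SequenceRecord(id=rec.id, sequence=seq, label=int(label)))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path), "fasta",
    )


def write_manifest(records: Sequence[SequenceRecord], path: str | Path, seed: int | None = None) -> None:
    """Write a TSV manifest (id, label, length, seed) next to the FASTA output."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\tlength\tseed\n")
        for r in records:
            fh.write(f"{r.id}\t{r.label}\t{r.length}\t{'' if seed is None else seed}\n")


def one_hot_encode(record: SequenceRecord | str, policy: str = "strict") -> np.ndarray:
    """Encode a sequence as an L x 4 binary matrix, column order (A, C, G, T).

    Each nucleotide maps to its 4-dimensional indicator vector, so every row
    sums to 1.  Under ``policy="zeros"`` ambiguous characters become all-zero
    rows instead of raising.
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    rid = record.id if isinstance(record, SequenceRecord) else "<anonymous>"
    seq = _validate_sequence(seq, rid, policy)
    mat = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq):
        j = _BASE_INDEX.get(ch)
        if j is not None:
            mat[i, j] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` via per-row argmax."""
    return "".join(ALPHABET[j] for j in np.argmax(mat, axis=1))


def encode_batch(records: Sequence[SequenceRecord], policy: str = "strict") -> tuple[np.ndarray, np.ndarray]:
    """Stack one-hot matrices as (B, 4, L) plus the (B,) label vector."""
    lengths = {r.length for r in records}
    if len(lengths) > 1:
        raise ValidationError(f"records have mixed lengths {sorted(lengths)}")
    X = np.stack([one_hot_encode(r, policy).T for r in records]).astype(np.float32)
    y = np.array([r.label for r in records], dtype=np.int64)
    return X, y


def generate_synthetic(spec: SyntheticSpec) -> list[SequenceRecord]:
    """Draw a synthetic dataset; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background, dtype=float)
    bg = bg / bg.sum()
    records: list[SequenceRecord] = []

    def draw_background(n: int) -> np.ndarray:
        return rng.choice(4, size=(n, spec.length), p=bg)

    pos = draw_background(spec.n_pos)
    for m in spec.motifs:
        core = np.array([_BASE_INDEX[c] for c in m.consensus])
        span = slice(m.offset, m.offset + len(core))
        pos[:, span] = core
        if m.sub_prob > 0:
            hit = rng.random((spec.n_pos, len(core))) < m.sub_prob
            # substitute uniformly over the other three bases
            shift = rng.integers(1, 4, size=hit.shape)
            sub = (pos[:, span] + shift) % 4
            pos[:, span] = np.where(hit, sub, pos[:, span])
    neg = draw_background(spec.n_neg)

    for i, row in enumerate(pos):
        records.append(SequenceRecord(f"pos_{i}", "".join(ALPHABET[j] for j in row), 1))
    for i, row in enumerate(neg):
        records.append(SequenceRecord(f"neg_{i}", "".join(ALPHABET[j] for j in row), 0))
    return records


@dataclasses.dataclass
class FoldAssignment:
    """A partition of record indices into K folds."""

    fold_of: np.ndarray  # (n,) int fold id
    K: int

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == k)


def kfold_split(labels: Sequence[int], K: int, seed: int = 0, stratified: bool = True) -> FoldAssignment:
    """Assign each index to one of K folds.

    Fold sizes differ by at most 1; with ``stratified`` (the default) each
    class is additionally spread so per-fold class counts differ from exact
    proportionality by at most 1.  Deterministic given ``seed``.
    """
    y = np.asarray(labels)
    n = len(y)
    if K < 2:
        raise ValidationError("K must be >= 2")
    if K > n:
        raise ValidationError(f"K={K} exceeds number of records n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if stratified:
        # Deal a single round-robin stream across classes: per-class counts
        # and total fold sizes each differ by at most 1.
        pointer = 0
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for i in idx:
                fold_of[i] = pointer % K
                pointer += 1
    else:
        idx = rng.permutation(n)
        for pos, i in enumerate(idx):
            fold_of[i] = pos % K
    return FoldAssignment(fold_of=fold_of, K=K)
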