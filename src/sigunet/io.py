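"""Reading, writing and encoding protein N-terminal sequences.

Sequences come in as plain FASTA; per-residue annotations use a two-line
dialect (FASTA-style header, sequence line, label line over ``{S, T, N}``)
where ``S`` marks signal-peptide residues, ``T`` transmembrane residues and
``N`` everything else.  The network consumes a fixed window of the first 96
residues, one-hot encoded over the 20 standard amino acids in alphabetical
order ``ACDEFGHIKLMNPQRSTVWY``; ambiguity letters (X, B, Z, U, O) become
all-zero rows, and short sequences are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

INPUT_LENGTH = 96
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = "XBZUO"
LABEL_ALPHABET = "STN"
#: output channel order: signal peptide, transmembrane, neither
CLASSES = ("S", "T", "N")

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_VALID_CHARS = frozenset(ALPHABET + AMBIGUOUS)


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class ProteinRecord:
    """A protein sequence with optional per-residue S/T/N labels."""

    id: str
    sequence: str
    labels: str | None = None
    group: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid sequence characters {sorted(bad)}"
            )
        if self.labels is not None:
            if len(self.labels) != len(self.sequence):
                raise FormatError(
                    f"record {self.id!r}: label length {len(self.labels)} != "
                    f"sequence length {len(self.sequence)}"
                )
            bad = set(self.labels) - set(LABEL_ALPHABET)
            if bad:
                raise FormatError(
                    f"record {self.id!r}: invalid label characters {sorted(bad)}"
                )

    @property
    def is_sp(self) -> bool | None:
        """Protein-level signal-peptide status: labels begin with 'S'."""
        if self.labels is None:
            return None
        return self.labels.startswith("S")

    @property
    def is_tm(self) -> bool | None:
        """Transmembrane negative: a 'T' within the first 70 positions, no 'S'."""
        if self.labels is None:
            return None
        return "T" in self.labels[:70] and "S" not in self.labels


@dataclass
class EncodedSample:
    """One protein encoded for the network: 96x20 input, optional 96x3 target."""

    x: np.ndarray
    y: np.ndarray | None = None
    source_id: str = ""
    true_is_sp: bool | None = None
    true_is_tm: bool | None = None
    #: number of real (non-padding) positions within the 96-window
    n_real: int = INPUT_LENGTH


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into records (no labels).

    The record id is the first whitespace-delimited token of the header and
    sequences are upper-cased.  Characters outside the amino-acid alphabet
    plus ambiguity letters raise :class:`FormatError`.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        rid = header.split()[0] if header.split() else header
        if not seq:
            raise FormatError(f"record {rid!r}: empty sequence")
        records.append(ProteinRecord(id=rid, sequence=seq))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_annotations(path: str | Path) -> list[ProteinRecord]:
    """Read the two-line annotation dialect: header, sequence line, label line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    records: list[ProteinRecord] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"expected header at line {i + 1}, got {lines[i]!r}")
        header = lines[i][1:]
        rid = header.split()[0] if header.split() else header
        if i + 2 >= len(lines):
            raise FormatError(f"record {rid!r}: truncated entry")
        seq, lab = lines[i + 1].upper(), lines[i + 2]
        records.append(ProteinRecord(id=rid, sequence=seq, labels=lab))
        i += 3
    return records


def write_annotations(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.labels is None:
                raise ValueError(f"record {rec.id!r} has no labels")
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.labels}\n")


def encode_sequence(record: ProteinRecord) -> np.ndarray:
    """One-hot encode the first 96 residues into a 96x20 binary matrix.

    Ambiguity letters give all-zero rows; positions past the sequence end
    are zero padding; residues beyond position 96 are discarded.
    """
    if len(record.sequence) < 1:
        raise ValueError("empty sequence")
    x = np.zeros((INPUT_LENGTH, len(ALPHABET)), dtype=np.float64)
    for i, aa in enumerate(record.sequence[:INPUT_LENGTH]):
        j = _AA_INDEX.get(aa)
        if j is not None:
            x[i, j] = 1.0
    return x


def encode_labels(record: ProteinRecord) -> np.ndarray:
    """Encode S/T/N labels as a 96x3 one-hot matrix (channel order S, T, N).

    Padded positions beyond the sequence length are encoded as class N so
    every row is a valid one-hot vector.
    """
    if record.labels is None:
        raise ValueError(f"record {record.id!r} has no labels")
    y = np.zeros((INPUT_LENGTH, 3), dtype=np.float64)
    n_class = CLASSES.index("N")
    for i in range(INPUT_LENGTH):
        if i < len(record.labels):
            y[i, CLASSES.index(record.labels[i])] = 1.0
        else:
            y[i, n_class] = 1.0
    return y


def encode_records(records: Sequence[ProteinRecord]) -> list[EncodedSample]:
    """Encode records into network samples, deriving protein-level flags."""
    samples = []
    for rec in records:
        samples.append(
            EncodedSample(
                x=encode_sequence(rec),
                y=encode_labels(rec) if rec.labels is not None else None,
                source_id=rec.id,
                true_is_sp=rec.is_sp,
                true_is_tm=rec.is_tm,
                n_real=min(len(rec.sequence), INPUT_LENGTH),
            )
        )
    return samples
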