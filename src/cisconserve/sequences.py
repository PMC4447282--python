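"""Sequence data model, FASTA I/O, and strand primitives.

Upstream non-coding regions are represented as validated uppercase DNA
strings over {A,C,G,T,N}.  Because functional positions are conventionally
reported relative to the translation start (negative upstream of the ATG),
a sequence may carry the 0-based index of the first base of its start
codon, and positions can be converted between internal 0-based coordinates
and ATG-relative coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Union

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

VALID_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequences or FASTA records."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence, optionally anchored at its translation start.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        Uppercase DNA over {A,C,G,T,N}; non-empty.
    atg_offset : int, optional
        0-based index of the first base of the start codon within
        ``residues``.  Positions upstream of the ATG are negative in
        ATG-relative coordinates.
    """

    id: str
    residues: str
    atg_offset: int | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r}: empty residues")
        for i, ch in enumerate(self.residues):
            if ch not in VALID_RESIDUES:
                raise SequenceError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {i + 1}"
                )
        if self.atg_offset is not None and not (0 <= self.atg_offset <= len(self.residues)):
            raise SequenceError(
                f"sequence {self.id!r}: atg_offset {self.atg_offset} outside [0, {len(self.residues)}]"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(
            id=self.id, residues=reverse_complement(self.residues), atg_offset=None
        )


SequenceLike = Union[str, NucleotideSequence]


def as_residues(seq: SequenceLike) -> str:
    """Residue string of a NucleotideSequence, or a plain string as-is."""
    if isinstance(seq, NucleotideSequence):
        return seq.residues
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N complements to N."""
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise SequenceError(f"illegal residue(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_residues(raw: str, record_id: str = "<anonymous>") -> str:
    """Uppercase, convert U to T, and validate a raw residue string.

    Position in error messages is 1-based, matching FASTA viewer convention.
    """
    up = raw.upper().replace("U", "T")
    for i, ch in enumerate(up):
        if ch not in VALID_RESIDUES:
            raise SequenceError(
                f"record {record_id!r}: illegal residue {raw[i]!r} at position {i + 1}"
            )
    return up


def read_fasta(path: str | os.PathLike) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into validated sequences.

    Residues are uppercased and U is converted to T.  Any other character
    outside {A,C,G,T,N} raises :class:`SequenceError` naming the record and
    the 1-based offending position.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        out.append(NucleotideSequence(id=rec.id, residues=normalize_residues(str(rec.seq), rec.id)))
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def to_atg_relative(position: int, seq: NucleotideSequence) -> int:
    """Convert a 0-based internal position to an ATG-relative coordinate.

    The base at the atg_offset itself maps to 0; upstream positions are
    negative.
    """
    if seq.atg_offset is None:
        raise SequenceError(f"sequence {seq.id!r}: atg_offset is not set")
    return position - seq.atg_offset


def from_atg_relative(relative: int, seq: NucleotideSequence) -> int:
    """Inverse of :func:`to_atg_relative`."""
    if seq.atg_offset is None:
        raise SequenceError(f"sequence {seq.id!r}: atg_offset is not set")
    return relative + seq.atg_offset
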