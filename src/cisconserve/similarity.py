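"""Alignment-free similarity statistics between a reference element and an ortholog.

Two upstream regulatory regions are compared by exact k-mer matching only:
dotplot match points in direct and reverse-complement orientation, counts
of shared k-mers, the fraction of the query covered by windows shared with
the reference, and maximal exact shared blocks with a low-complexity flag.
No gapped alignment or scoring matrices are involved; identity of short
windows is the entire signal, which is what makes the composition-
preserving shuffle null (see :mod:`cisconserve.shuffling`) the appropriate
significance reference.

Coordinates are 0-based, half-open.  A "reverse" match at (i, j) means
``reference[i:i+k] == reverse_complement(query[j:j+k])``; plain reversal
without complementation is deliberately not offered.  Windows containing N
never match anything.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sequences import SequenceLike, as_residues, reverse_complement

DIRECT = "direct"
REVERSE = "reverse"
BOTH = (DIRECT, REVERSE)

DISTINCT_KMERS = "distinct_kmers"
MATCH_PAIRS = "match_pairs"


@dataclass(frozen=True, order=True)
class MatchPoint:
    """An exact k-mer match between reference and query."""

    ref_pos: int
    query_pos: int
    k: int
    orientation: str


@dataclass(frozen=True, order=True)
class SharedBlock:
    """A maximal exact shared block (not extendable at either end)."""

    ref_pos: int
    query_pos: int
    length: int
    orientation: str
    sequence: str
    low_complexity: bool


@dataclass(frozen=True)
class CoverageProfile:
    """Per-k fraction of the query covered by windows shared with the reference."""

    window_sizes: tuple[int, ...]
    fractions: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.window_sizes, "fraction": self.fractions})


def _check_orientations(orientations: Iterable[str]) -> tuple[str, ...]:
    ors = tuple(orientations)
    for o in ors:
        if o not in BOTH:
            raise ValueError(f"unknown orientation {o!r}")
    if not ors:
        raise ValueError("at least one orientation required")
    return ors


def _kmer_positions(s: str, k: int) -> dict[str, list[int]]:
    """Positions of each N-free k-mer."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _kmer_set(s: str, k: int) -> set[str]:
    return {
        s[i : i + k]
        for i in range(len(s) - k + 1)
        if "N" not in s[i : i + k]
    }


def dotplot_matches(
    reference: SequenceLike,
    query: SequenceLike,
    k: int,
    orientations: Iterable[str] = BOTH,
) -> list[MatchPoint]:
    """All exact k-window matches between reference and query.

    Returns every position pair (i, j) where the reference window equals
    the query window (direct) or its reverse complement (reverse), the
    point set a dotplot displays.
    """
    ref = as_residues(reference)
    qry = as_residues(query)
    ors = _check_orientations(orientations)
    if k < 1 or k > min(len(ref), len(qry)):
        raise ValueError(f"k={k} out of range for sequence lengths {len(ref)}, {len(qry)}")
    ref_index = _kmer_positions(ref, k)
    points: list[MatchPoint] = []
    for j in range(len(qry) - k + 1):
        window = qry[j : j + k]
        if "N" in window:
            continue
        if DIRECT in ors:
            for i in ref_index.get(window, ()):
                points.append(MatchPoint(i, j, k, DIRECT))
        if REVERSE in ors:
            for i in ref_index.get(reverse_complement(window), ()):
                points.append(MatchPoint(i, j, k, REVERSE))
    points.sort()
    return points


def count_shared_kmers(
    reference: SequenceLike,
    query: SequenceLike,
    k: int,
    convention: str = DISTINCT_KMERS,
    orientations: Iterable[str] = BOTH,
) -> int:
    """Number of k-mers shared between reference and query.

    Under ``distinct_kmers`` (default): the number of distinct k-mer
    strings of the reference that occur in the query in any requested
    orientation, robust to internal repeats.  Under ``match_pairs``: the
    number of match points (dotplot dots).
    """
    ors = _check_orientations(orientations)
    if convention == MATCH_PAIRS:
        return len(dotplot_matches(reference, query, k, ors))
    if convention != DISTINCT_KMERS:
        raise ValueError(f"unknown convention {convention!r}")
    ref = as_residues(reference)
    qry = as_residues(query)
    if k < 1 or k > min(len(ref), len(qry)):
        raise ValueError(f"k={k} out of range for sequence lengths {len(ref)}, {len(qry)}")
    ref_kmers = _kmer_set(ref, k)
    # a reference k-mer matching a query window in reverse orientation is a
    # k-mer of the reverse-complemented query
    query_space: set[str] = set()
    if DIRECT in ors:
        query_space |= _kmer_set(qry, k)
    if REVERSE in ors:
        query_space |= _kmer_set(reverse_complement(qry), k)
    return len(ref_kmers & query_space)


def coverage_fraction(
    query: SequenceLike,
    reference: SequenceLike,
    k: int,
    orientations: Iterable[str] = BOTH,
) -> float:
    """Fraction of query positions under at least one shared k-window.

    A query position is covered when some length-k window of the query
    containing it occurs in the reference in a requested orientation.
    """
    ref = as_residues(reference)
    qry = as_residues(query)
    ors = _check_orientations(orientations)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(qry):
        warnings.warn(f"k={k} exceeds query length {len(qry)}; coverage is 0 by convention")
        return 0.0
    ref_kmers = _kmer_set(ref, min(k, len(ref))) if k <= len(ref) else set()
    covered = bytearray(len(qry))
    for j in range(len(qry) - k + 1):
        window = qry[j : j + k]
        if "N" in window:
            continue
        hit = (DIRECT in ors and window in ref_kmers) or (
            REVERSE in ors and reverse_complement(window) in ref_kmers
        )
        if hit:
            for p in range(j, j + k):
                covered[p] = 1
    return sum(covered) / len(qry)


def coverage_profile(
    query: SequenceLike,
    reference: SequenceLike,
    window_sizes: Sequence[int],
    orientations: Iterable[str] = BOTH,
) -> CoverageProfile:
    """Coverage fractions across a range of window sizes (dotplot companion curve)."""
    fracs = tuple(coverage_fraction(query, reference, k, orientations) for k in window_sizes)
    return CoverageProfile(tuple(window_sizes), fracs)


def low_complexity_flag(block_sequence: str) -> bool:
    """Flag compositionally simple blocks.

    A block is low-complexity when (a) its longest single-nucleotide run
    spans at least 60% of its length, or (b) it contains at most 3
    distinct dinucleotides — a simple proxy for homopolymers and short
    tandem repeats, which dominate long chance identities in AT-biased
    non-coding DNA.
    """
    s = block_sequence
    if not s:
        raise ValueError("empty block sequence")
    longest = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    if longest >= 0.6 * len(s):
        return True
    dinucs = {s[i : i + 2] for i in range(len(s) - 1)}
    return len(dinucs) <= 3


def _extend_match(ref: str, qry: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximal extension of the seed match ref[i:i+k] == qry[j:j+k].

    Returns (ref_start, query_start, length).  N never matches N.
    """
    lo_i, lo_j = i, j
    while lo_i > 0 and lo_j > 0 and ref[lo_i - 1] == qry[lo_j - 1] and ref[lo_i - 1] != "N":
        lo_i -= 1
        lo_j -= 1
    hi_i, hi_j = i + k, j + k
    while (
        hi_i < len(ref)
        and hi_j < len(qry)
        and ref[hi_i] == qry[hi_j]
        and ref[hi_i] != "N"
    ):
        hi_i += 1
        hi_j += 1
    return lo_i, lo_j, hi_i - lo_i


def _maximal_blocks_direct(ref: str, qry: str, min_length: int) -> set[tuple[int, int, int]]:
    """Maximal exact blocks of length >= min_length, as (ref_pos, qry_pos, length).

    Seed-and-extend: every maximal block of length >= min_length contains a
    seed of length min_length on its diagonal, so extending every seed and
    deduplicating yields exactly the maximal set.
    """
    k = min_length
    ref_index = _kmer_positions(ref, k) if k <= len(ref) else {}
    blocks: set[tuple[int, int, int]] = set()
    for j in range(len(qry) - k + 1):
        window = qry[j : j + k]
        if "N" in window:
            continue
        for i in ref_index.get(window, ()):
            blocks.add(_extend_match(ref, qry, i, j, k))
    return blocks


def maximal_shared_blocks(
    reference: SequenceLike,
    query: SequenceLike,
    min_length: int,
    orientations: Iterable[str] = BOTH,
) -> list[SharedBlock]:
    """All maximal exact shared blocks of length >= min_length.

    Maximality is per orientation: extending a block one base in either
    direction breaks identity or runs off a sequence end.  Overlapping and
    nested blocks on different diagonals are all reported.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    ref = as_residues(reference)
    qry = as_residues(query)
    ors = _check_orientations(orientations)
    out: list[SharedBlock] = []
    if DIRECT in ors:
        for i, j, length in _maximal_blocks_direct(ref, qry, min_length):
            seq = ref[i : i + length]
            out.append(SharedBlock(i, j, length, DIRECT, seq, low_complexity_flag(seq)))
    if REVERSE in ors:
        rcq = reverse_complement(qry)
        for i, jrc, length in _maximal_blocks_direct(ref, rcq, min_length):
            j = len(qry) - jrc - length
            seq = ref[i : i + length]
            out.append(SharedBlock(i, j, length, REVERSE, seq, low_complexity_flag(seq)))
    out.sort()
    return out


def matches_to_frame(points: Iterable[MatchPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.ref_pos, p.ref_pos + p.k, p.query_pos, p.query_pos + p.k, p.orientation) for p in points],
        columns=["ref_start", "ref_end", "query_start", "query_end", "orientation"],
    )


def blocks_to_frame(blocks: Iterable[SharedBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                b.ref_pos,
                b.ref_pos + b.length,
                b.query_pos,
                b.query_pos + b.length,
                b.length,
                b.orientation,
                b.sequence,
                b.low_complexity,
            )
            for b in blocks
        ],
        columns=[
            "ref_start",
            "ref_end",
            "query_start",
            "query_end",
            "length",
            "orientation",
            "sequence",
            "low_complexity",
        ],
    )
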