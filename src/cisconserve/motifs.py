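"""Consensus transcription-factor motif scanning and in-silico site mutagenesis.

A motif is a short consensus string (IUPAC degeneracy allowed), e.g.
TAATCC for the UNC-30 homeodomain site or CACGC for the AHR-1-like site.
Scanning reports every window matching with at most the allowed number of
Hamming mismatches, on either strand; minus-strand hits carry the plus-
strand coordinates of the matched window, so overlapping palindromic pairs
(e.g. the two CACGC instances inside CACGCGTG) appear as two distinct
hits.  N in the scanned sequence always counts as a mismatch.

Flanking-identity extension scores how far exact identity continues
outward from a shared core occurrence in two orthologs, the quantity
conventionally rendered as lowercase flanks around an uppercase core.

Site mutagenesis is substitution-only (as in reporter-construct
engineering); a mutation design is verified by rescanning a window around
the edited interval on both strands and reporting any surviving consensus
match.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .sequences import (
    NucleotideSequence,
    SequenceLike,
    as_residues,
    reverse_complement,
)

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

PLUS = "+"
MINUS = "-"


def iupac_reverse_complement(consensus: str) -> str:
    return consensus.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A named consensus motif with a mismatch budget."""

    name: str
    consensus: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name!r}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name!r}: illegal consensus symbol(s) {sorted(bad)}")
        if not (0 <= self.max_mismatches < len(self.consensus)):
            raise ValueError(
                f"motif {self.name!r}: max_mismatches must be in [0, {len(self.consensus) - 1}]"
            )
        object.__setattr__(self, "consensus", self.consensus.upper())

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True, order=True)
class MotifHit:
    """A consensus occurrence.

    ``position`` is the 0-based start of the matched window on the +
    strand; ``matched_sequence`` is given motif-forward (reverse-
    complemented for minus-strand hits).  Flank fields are filled by
    :func:`flank_extension` when a reference occurrence is available.
    """

    position: int
    strand: str
    mismatches: int
    matched_sequence: str
    flank_left: int | None = None
    flank_right: int | None = None


def _mismatch_count(window: str, consensus: str, budget: int) -> int | None:
    """Hamming mismatches of window vs IUPAC consensus; None if over budget."""
    mm = 0
    for ch, code in zip(window, consensus):
        if ch == "N" or ch not in IUPAC[code]:
            mm += 1
            if mm > budget:
                return None
    return mm


def scan_consensus(
    seq: SequenceLike,
    motif: MotifSpec,
    strands: str = "both",
) -> list[MotifHit]:
    """All occurrences of the consensus with at most max_mismatches.

    ``strands`` is one of ``both``, ``plus``, ``minus``.  Overlapping hits
    and per-strand duplicates of palindromes are reported separately.
    """
    if strands not in ("both", "plus", "minus"):
        raise ValueError(f"unknown strand mode {strands!r}")
    s = as_residues(seq)
    w = len(motif)
    if w > len(s):
        warnings.warn(f"motif {motif.name!r} (width {w}) longer than sequence ({len(s)} nt)")
        return []
    minus_consensus = iupac_reverse_complement(motif.consensus)
    hits: list[MotifHit] = []
    for pos in range(len(s) - w + 1):
        window = s[pos : pos + w]
        if strands in ("both", "plus"):
            mm = _mismatch_count(window, motif.consensus, motif.max_mismatches)
            if mm is not None:
                hits.append(MotifHit(pos, PLUS, mm, window))
        if strands in ("both", "minus"):
            mm = _mismatch_count(window, minus_consensus, motif.max_mismatches)
            if mm is not None:
                hits.append(MotifHit(pos, MINUS, mm, reverse_complement(window)))
    hits.sort()
    return hits


def flank_extension(
    ref_context: str,
    query_context: str,
    core_start: int,
    core_length: int,
) -> tuple[int, int]:
    """Greedy identity extension outward from a shared core occurrence.

    Both contexts must be aligned on the core start (index ``core_start``
    in each, core occupying ``core_start:core_start+core_length``).
    Comparison is case-insensitive; minus-strand query hits should be
    passed in their motif-forward orientation.  Returns (left, right)
    numbers of identical flanking bases.
    """
    ref = ref_context.upper()
    qry = query_context.upper()
    if core_start < 0 or core_start + core_length > min(len(ref), len(qry)):
        raise ValueError("context shorter than core")
    left = 0
    i = core_start - 1
    while i >= 0 and ref[i] == qry[i] and ref[i] != "N":
        left += 1
        i -= 1
    right = 0
    i = core_start + core_length
    while i < min(len(ref), len(qry)) and ref[i] == qry[i] and ref[i] != "N":
        right += 1
        i += 1
    return left, right


def _search_patterns(motif: MotifSpec, strands: str) -> list[re.Pattern]:
    """Compiled regexes for exact (0-mismatch) occurrence on the requested strands."""

    def to_regex(consensus: str) -> re.Pattern:
        return re.compile("".join(f"[{''.join(sorted(IUPAC[c]))}]" for c in consensus))

    pats = []
    if strands in ("both", "plus"):
        pats.append(to_regex(motif.consensus))
    if strands in ("both", "minus"):
        pats.append(to_regex(iupac_reverse_complement(motif.consensus)))
    return pats


def motif_null_probability(
    seq: SequenceLike,
    motif: MotifSpec,
    order: int,
    n_replicates: int = 1000,
    seed: int = 0,
    strands: str = "both",
    method: str | None = None,
) -> float:
    """Chance probability of at least one exact motif occurrence.

    The sequence is reshuffled preserving its composition at the given
    order; the returned value is the fraction of replicates containing at
    least one exact (0-mismatch) consensus occurrence on the requested
    strands.
    """
    from . import shuffling

    s = as_residues(seq)
    pats = _search_patterns(motif, strands)
    rng = np.random.default_rng(seed)
    kw = {"method": method} if method else {}
    found = 0
    for _ in range(n_replicates):
        rep = shuffling.shuffle_preserving_klets(s, order, rng, **kw)
        if any(p.search(rep) for p in pats):
            found += 1
    return found / n_replicates


@dataclass(frozen=True)
class MutationReport:
    """Outcome of verifying a site mutation design."""

    interval: tuple[int, int]
    replacement: str
    surviving_hits: tuple[MotifHit, ...]

    @property
    def ok(self) -> bool:
        return not self.surviving_hits


def apply_site_mutation(
    seq: SequenceLike,
    interval: tuple[int, int],
    replacement: str,
    verify_against: MotifSpec,
) -> tuple[str | NucleotideSequence, MutationReport]:
    """Substitute an interval and verify the target consensus is destroyed.

    ``interval`` is 0-based half-open and the replacement must have the
    same length (substitution-only mutagenesis).  Verification rescans a
    window spanning the interval extended by one motif length on each
    side, on both strands, for exact consensus matches; a valid design has
    none surviving.
    """
    s = as_residues(seq)
    start, end = interval
    if not (0 <= start < end <= len(s)):
        raise ValueError(f"interval {interval} out of bounds for length {len(s)}")
    if len(replacement) != end - start:
        raise ValueError(
            f"replacement length {len(replacement)} != interval length {end - start} "
            "(substitution-only mutagenesis)"
        )
    replacement_up = replacement.upper()
    mutated = s[:start] + replacement_up + s[end:]
    w = len(verify_against)
    win_start = max(0, start - w)
    win_end = min(len(mutated), end + w)
    window = mutated[win_start:win_end]
    exact = MotifSpec(verify_against.name, verify_against.consensus, 0)
    survivors = tuple(
        MotifHit(h.position + win_start, h.strand, h.mismatches, h.matched_sequence)
        for h in scan_consensus(window, exact, strands="both")
    )
    report = MutationReport((start, end), replacement_up, survivors)
    if isinstance(seq, NucleotideSequence):
        return (
            NucleotideSequence(id=seq.id + "_mut", residues=mutated, atg_offset=seq.atg_offset),
            report,
        )
    return mutated, report


def batch_scan(
    seqs: Iterable[SequenceLike],
    motifs: Iterable[MotifSpec],
    strands: str = "both",
) -> pd.DataFrame:
    """Scan every element against every motif (cross-element lookup table)."""
    rows = []
    for seq in seqs:
        sid = seq.id if isinstance(seq, NucleotideSequence) else "<anonymous>"
        for motif in motifs:
            for hit in scan_consensus(seq, motif, strands):
                atg_rel = None
                if isinstance(seq, NucleotideSequence) and seq.atg_offset is not None:
                    atg_rel = hit.position - seq.atg_offset
                rows.append(
                    (
                        sid,
                        motif.name,
                        hit.position,
                        hit.position + len(motif),
                        atg_rel,
                        hit.strand,
                        hit.mismatches,
                        hit.matched_sequence,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "motif",
            "start",
            "end",
            "atg_relative_start",
            "strand",
            "mismatches",
            "matched_sequence",
        ],
    )


def hits_to_frame(hits: Iterable[MotifHit], motif: MotifSpec) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.position, h.position + len(motif), h.strand, h.mismatches, h.matched_sequence)
            for h in hits
        ],
        columns=["start", "end", "strand", "mismatches", "matched_sequence"],
    )
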