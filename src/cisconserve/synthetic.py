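"""Generators for synthetic ortholog pairs and reporter count tables.

Two divergence regimes are emulated, mirroring what real upstream regions
look like at small and large phylogenetic distance:

``congeneric``
    The query carries collinear blocks copied verbatim from the reference
    (plus shared motifs) over independent background — the signature of a
    recently diverged pair: a dotplot diagonal and an excess of shared
    k-mers over the composition null.

``deep``
    Reference and query share nothing but short planted motif instances,
    possibly strand-flipped, shifted and degenerate — motif content
    without sequence conservation, the regime in which similarity
    statistics must NOT reject the shuffle null.

Backgrounds default to AT-rich composition (A=T=0.32, C=G=0.18),
emulating nematode non-coding DNA, where biased composition inflates
chance matches.  Every generator is deterministic given its seed, and a
truth record of all planted coordinates accompanies each pair so recovery
can be asserted exactly.

Reporter count tables are generated per animal: mCherry cells binomially
with the control construct's expression probability, GFP cells with the
test construct's, over the anatomical maximum for the cell class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import NucleotideSequence, reverse_complement
from .reporter import ReporterCountTable

BASES = "ACGT"
# AT-rich default emulating nematode non-coding DNA
AT_RICH = {"A": 0.32, "C": 0.18, "G": 0.18, "T": 0.32}


@dataclass(frozen=True)
class PlantedBlock:
    length: int
    ref_pos: int
    query_pos: int
    orientation: str = "direct"


@dataclass(frozen=True)
class PlantedMotif:
    consensus: str
    query_pos: int
    strand: str = "+"
    mismatches: int = 0


@dataclass(frozen=True)
class OrthologScenario:
    """Recipe for a synthetic reference/query ortholog pair."""

    scenario: str  # "congeneric" | "deep"
    length_ref: int = 1500
    length_query: int = 1500
    base_frequencies: Mapping[str, float] = field(default_factory=lambda: dict(AT_RICH))
    conserved_blocks: tuple[PlantedBlock, ...] = ()
    planted_motifs: tuple[PlantedMotif, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("congeneric", "deep"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "deep" and self.conserved_blocks:
            raise ValueError("deep scenario must not plant conserved blocks")
        intervals = [(b.query_pos, b.query_pos + b.length) for b in self.conserved_blocks]
        intervals += [(m.query_pos, m.query_pos + len(m.consensus)) for m in self.planted_motifs]
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError(f"planted features overlap: [{s1},{e1}) and [{s2},{e2})")
        for s, e in intervals:
            if s < 0 or e > self.length_query:
                raise ValueError(f"planted feature [{s},{e}) outside query bounds")
        for b in self.conserved_blocks:
            if b.ref_pos < 0 or b.ref_pos + b.length > self.length_ref:
                raise ValueError("planted block outside reference bounds")


@dataclass(frozen=True)
class TruthRecord:
    """Exact coordinates of everything planted into a generated pair."""

    blocks: tuple[PlantedBlock, ...]
    motifs: tuple[PlantedMotif, ...]
    motif_sequences: tuple[str, ...]  # realised instance (after mismatches), motif-forward

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("block", b.ref_pos, b.query_pos, b.length, b.orientation, "")
            for b in self.blocks
        ]
        rows += [
            ("motif", -1, m.query_pos, len(m.consensus), m.strand, seq)
            for m, seq in zip(self.motifs, self.motif_sequences)
        ]
        return pd.DataFrame(
            rows, columns=["feature", "ref_pos", "query_pos", "length", "orientation", "sequence"]
        )


def _freq_arrays(frequencies: Mapping[str, float]) -> np.ndarray:
    probs = np.array([frequencies.get(b, 0.0) for b in BASES], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"base frequencies must be non-negative and sum to 1, got {frequencies}")
    return probs / probs.sum()


def generate_background(
    length: int,
    frequencies: Mapping[str, float] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    seq_id: str = "background",
) -> NucleotideSequence:
    """I.i.d. background sequence of the requested composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    probs = _freq_arrays(frequencies or AT_RICH)
    if rng is None:
        rng = np.random.default_rng(seed)
    draw = rng.choice(4, size=length, p=probs)
    residues = "".join(BASES[i] for i in draw)
    return NucleotideSequence(id=seq_id, residues=residues)


def _mutate_positions(instance: str, n_mismatches: int, rng: np.random.Generator) -> str:
    if n_mismatches == 0:
        return instance
    if n_mismatches >= len(instance):
        raise ValueError("mismatches must be fewer than motif length")
    positions = rng.choice(len(instance), size=n_mismatches, replace=False)
    chars = list(instance)
    for p in positions:
        alternatives = [b for b in BASES if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(3))]
    return "".join(chars)


def generate_ortholog_pair(
    scenario: OrthologScenario,
) -> tuple[NucleotideSequence, NucleotideSequence, TruthRecord]:
    """Reference, query, and exact truth record for a scenario.

    Congeneric: the query carries the listed blocks copied verbatim from
    the reference at the listed (collinear) positions.  Deep: the query
    shares only the planted motif instances.  Motif instances may be
    strand-flipped and carry planted mismatches; the realised instance is
    recorded motif-forward in the truth record.
    """
    rng = np.random.default_rng(scenario.seed)
    ref = generate_background(
        scenario.length_ref, scenario.base_frequencies, rng=rng, seq_id="reference"
    )
    query_chars = list(
        generate_background(
            scenario.length_query, scenario.base_frequencies, rng=rng, seq_id="query"
        ).residues
    )
    for b in scenario.conserved_blocks:
        segment = ref.residues[b.ref_pos : b.ref_pos + b.length]
        if b.orientation == "reverse":
            segment = reverse_complement(segment)
        query_chars[b.query_pos : b.query_pos + b.length] = segment
    realised: list[str] = []
    for m in scenario.planted_motifs:
        instance = _mutate_positions(m.consensus.upper(), m.mismatches, rng)
        realised.append(instance)
        embedded = instance if m.strand == "+" else reverse_complement(instance)
        query_chars[m.query_pos : m.query_pos + len(embedded)] = embedded
    query = NucleotideSequence(id="query", residues="".join(query_chars))
    truth = TruthRecord(scenario.conserved_blocks, scenario.planted_motifs, tuple(realised))
    return ref, query, truth


def congeneric_scenario(seed: int = 0) -> OrthologScenario:
    """Default recently-diverged pair: collinear conserved blocks plus shared motifs."""
    return OrthologScenario(
        scenario="congeneric",
        length_ref=1500,
        length_query=1500,
        conserved_blocks=(
            PlantedBlock(length=23, ref_pos=150, query_pos=160),
            PlantedBlock(length=18, ref_pos=480, query_pos=495),
            PlantedBlock(length=15, ref_pos=820, query_pos=840),
            PlantedBlock(length=20, ref_pos=1100, query_pos=1125),
        ),
        planted_motifs=(PlantedMotif("TAATCC", query_pos=300, strand="+"),),
        seed=seed,
    )


def deep_scenario(seed: int = 0) -> OrthologScenario:
    """Default deeply-diverged pair: motif content only, no conserved blocks."""
    return OrthologScenario(
        scenario="deep",
        length_ref=2000,
        length_query=2000,
        planted_motifs=(
            PlantedMotif("TAATCC", query_pos=400, strand="-"),
            PlantedMotif("TAATCC", query_pos=900, strand="+"),
            PlantedMotif("TAATCC", query_pos=1500, strand="-"),
        ),
        seed=seed,
    )


def generate_reporter_table(
    n_animals: int,
    expression_probs: Mapping[str, Mapping[str, tuple[float, float]]],
    max_cells: Mapping[str, int] | int,
    seed: int = 0,
) -> ReporterCountTable:
    """Synthetic per-animal reporter counts.

    ``expression_probs[construct][cell_class] = (p_gfp, p_mcherry)``; per
    animal, GFP and mCherry cell counts are binomial over the cell-class
    maximum with the respective probabilities.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for construct, classes in expression_probs.items():
        for animal in range(n_animals):
            for cell_class, (p_gfp, p_mch) in classes.items():
                if not (0 <= p_gfp <= 1 and 0 <= p_mch <= 1):
                    raise ValueError(
                        f"invalid probabilities ({p_gfp}, {p_mch}) for "
                        f"{construct}/{cell_class}"
                    )
                mx = max_cells[cell_class] if isinstance(max_cells, Mapping) else max_cells
                gfp = int(rng.binomial(mx, p_gfp))
                mch = int(rng.binomial(mx, p_mch))
                rows.append((f"{construct}_{animal}", construct, cell_class, gfp, mch, mx))
    df = pd.DataFrame(
        rows, columns=["animal", "construct", "cell_class", "gfp", "mcherry", "max_cells"]
    )
    return ReporterCountTable(df)
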