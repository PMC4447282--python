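"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive double loops and direct
formula transcriptions — and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def brute_dotplot(ref: str, qry: str, k: int, orientations=("direct", "reverse")):
    """All (i, j, orientation) window matches by exhaustive comparison."""
    out = set()
    for i in range(len(ref) - k + 1):
        rw = ref[i : i + k]
        if "N" in rw:
            continue
        for j in range(len(qry) - k + 1):
            qw = qry[j : j + k]
            if "N" in qw:
                continue
            if "direct" in orientations and rw == qw:
                out.add((i, j, "direct"))
            if "reverse" in orientations and rw == revcomp(qw):
                out.add((i, j, "reverse"))
    return out


def brute_coverage(qry: str, ref: str, k: int, orientations=("direct", "reverse")) -> float:
    """Coverage fraction by exhaustively marking covered query positions."""
    if k > len(qry):
        return 0.0
    ref_windows = {
        ref[i : i + k] for i in range(len(ref) - k + 1) if "N" not in ref[i : i + k]
    }
    covered = [False] * len(qry)
    for j in range(len(qry) - k + 1):
        qw = qry[j : j + k]
        if "N" in qw:
            continue
        hit = ("direct" in orientations and qw in ref_windows) or (
            "reverse" in orientations and revcomp(qw) in ref_windows
        )
        if hit:
            for p in range(j, j + k):
                covered[p] = True
    return sum(covered) / len(qry)


def _diagonal_runs(ref: str, qry: str, min_length: int):
    """Maximal exact blocks as runs of matching positions along each diagonal."""
    blocks = set()
    for d in range(-(len(qry) - 1), len(ref)):
        i0 = max(0, d)
        j0 = max(0, -d)
        run = 0
        i, j = i0, j0
        while i <= len(ref) and j <= len(qry):
            match = i < len(ref) and j < len(qry) and ref[i] == qry[j] and ref[i] != "N"
            if match:
                run += 1
            else:
                if run >= min_length:
                    blocks.add((i - run, j - run, run))
                run = 0
            i += 1
            j += 1
    return blocks


def brute_blocks(ref: str, qry: str, min_length: int, orientations=("direct", "reverse")):
    """Maximal shared blocks as (ref_pos, query_pos, length, orientation)."""
    out = set()
    if "direct" in orientations:
        for i, j, L in _diagonal_runs(ref, qry, min_length):
            out.add((i, j, L, "direct"))
    if "reverse" in orientations:
        rcq = revcomp(qry)
        for i, jrc, L in _diagonal_runs(ref, rcq, min_length):
            out.add((i, len(qry) - jrc - L, L, "reverse"))
    return out


def brute_scan(seq: str, consensus: str, max_mismatches: int, strands="both"):
    """All (position, strand, mismatches) consensus hits by direct comparison."""
    def mismatches(window: str, cons: str) -> int:
        return sum(
            1
            for ch, code in zip(window, cons)
            if ch == "N" or ch not in IUPAC_SETS[code]
        )

    cons_minus = "".join(
        {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}[c]
        for c in reversed(consensus)
    )
    w = len(consensus)
    hits = set()
    for pos in range(len(seq) - w + 1):
        window = seq[pos : pos + w]
        if strands in ("both", "plus"):
            mm = mismatches(window, consensus)
            if mm <= max_mismatches:
                hits.add((pos, "+", mm))
        if strands in ("both", "minus"):
            mm = mismatches(window, cons_minus)
            if mm <= max_mismatches:
                hits.add((pos, "-", mm))
    return hits


def hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """P(top-left cell = a) for fixed margins (r1, r2 rows; c1 first column)."""
    n = r1 + r2
    return (
        math.comb(r1, a) * math.comb(r2, c1 - a) / math.comb(n, c1)
    )


def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    p_obs = hypergeom_pmf(a, r1, r2, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom_pmf(x, r1, r2, c1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def ranksum_two_sided_enum(a, b) -> float:
    """Exact two-sided rank-sum p over all C(n+m, n) rank assignments."""
    n, m = len(a), len(b)
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    w_obs = sum(ranks[:n])
    mu = n * (n + m + 1) / 2.0
    dev = abs(w_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / total


def wilson_interval(x: int, n: int, z: float = 1.959963984540054):
    """Wilson score interval, transcribed directly from the closed form."""
    p = x / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half
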