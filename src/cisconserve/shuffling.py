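"""Composition-preserving sequence shuffles and empirical similarity nulls.

The central question this module answers: is the observed k-mer similarity
between a reference regulatory element and an ortholog more than would be
expected from the reference's nucleotide composition alone?  "Composition"
is preserved at order 1 (mononucleotide counts), 2 (dinucleotide counts)
or 3 (trinucleotide counts).

Two shuffle methods are provided:

``exact_klet`` (default)
    A uniformly random reordering that preserves the exact multiset of
    k-lets for k = order (and hence all shorter k-lets).  For order >= 2
    this is the random-Eulerian-path construction on the de Bruijn
    multigraph of (order-1)-mers: a uniform spanning arborescence toward
    the terminal vertex is drawn by Wilson's loop-erased random walk, the
    remaining out-edges of each vertex are permuted, and the walk that
    consumes the edges is the shuffled sequence.  The first and last
    (order-1)-mers are invariants of this construction.

``markov``
    An order-(k-1) Markov chain fitted to the input; k-let counts are
    preserved in expectation only.

The empirical p-value of an observed similarity count is the fraction of
shuffled replicates that score *strictly greater* than the observed value
(ties count as non-exceedances); zero is reportable and means "below 1/n".
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from functools import partial
from typing import Callable, Sequence

import numpy as np

from .sequences import SequenceLike, as_residues, reverse_complement
from . import similarity

EXACT_KLET = "exact_klet"
MARKOV = "markov"


@dataclass(frozen=True)
class ShuffleConfig:
    """Parameters of a shuffle-null run.

    order 1/2/3 preserves mono-/di-/trinucleotide composition;
    n_replicates defaults to 1000, the conventional depth for empirical
    p-values resolved to 0.001.
    """

    order: int = 3
    n_replicates: int = 1000
    seed: int = 0
    method: str = EXACT_KLET

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError(f"order must be 1, 2 or 3, got {self.order}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.method not in (EXACT_KLET, MARKOV):
            raise ValueError(f"unknown shuffle method {self.method!r}")


@dataclass(frozen=True)
class NullDistribution:
    """Replicate similarity counts, the observed count, and the empirical p."""

    replicate_counts: tuple[int, ...]
    observed: int
    empirical_p: float
    config: ShuffleConfig

    @property
    def annotation(self) -> str:
        if self.empirical_p == 0.0:
            return f"< {1 / len(self.replicate_counts):g}"
        return ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed": self.observed,
                "empirical_p": self.empirical_p,
                "annotation": self.annotation,
                "n_replicates": self.config.n_replicates,
                "order": self.config.order,
                "method": self.config.method,
                "seed": self.config.seed,
                "replicate_mean": float(np.mean(self.replicate_counts)),
            }
        )


def _eulerian_shuffle(s: str, order: int, rng: np.random.Generator) -> str:
    """Random Eulerian reordering preserving exact order-let counts (order >= 2)."""
    m = order - 1
    n_edges = len(s) - m
    # out-edge characters per (order-1)-mer vertex
    edges: dict[str, list[str]] = defaultdict(list)
    for i in range(n_edges):
        edges[s[i : i + m]].append(s[i + m])
    if all(len(set(chs)) <= 1 for chs in edges.values()) and all(
        len(chs) <= 1 for chs in edges.values()
    ):
        # every vertex has a single forced exit: the input is the only walk
        warnings.warn("degenerate de Bruijn graph: no alternative ordering exists")
        return s
    root = s[-m:]
    # Wilson's loop-erased random walk: uniform arborescence toward root.
    # Any non-root vertex has an out-edge (Eulerian path property), so the
    # walk can only terminate by reaching the tree.
    next_v: dict[str, str] = {}
    in_tree = {root}
    vertices = list(edges.keys())
    for v in vertices:
        u = v
        while u not in in_tree:
            chs = edges[u]
            c = chs[int(rng.integers(len(chs)))]
            next_v[u] = u[1:] + c
            u = next_v[u]
        u = v
        while u not in in_tree:
            in_tree.add(u)
            u = next_v[u]
    # Arrange out-edges: random order, with the arborescence edge exiting last.
    arranged: dict[str, list[str]] = {}
    for u, chs in edges.items():
        pool = list(chs)
        if u != root:
            last_char = next_v[u][-1]
            pool.remove(last_char)
            perm = rng.permutation(len(pool))
            pool = [pool[i] for i in perm]
            pool.append(last_char)
        else:
            perm = rng.permutation(len(pool))
            pool = [pool[i] for i in perm]
        arranged[u] = pool
    # Walk, consuming edges in arranged order.
    out = list(s[:m])
    ptr: dict[str, int] = defaultdict(int)
    cur = s[:m]
    for _ in range(n_edges):
        c = arranged[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(c)
        cur = cur[1:] + c
    return "".join(out)


def _markov_shuffle(s: str, order: int, rng: np.random.Generator) -> str:
    """Order-(order-1) Markov resample of the input (counts preserved in expectation)."""
    if order == 1:
        chars = np.array(list(s))
        counts = Counter(s)
        alphabet = sorted(counts)
        probs = np.array([counts[a] for a in alphabet], dtype=float)
        probs /= probs.sum()
        draw = rng.choice(len(alphabet), size=len(s), p=probs)
        return "".join(alphabet[i] for i in draw)
    m = order - 1
    trans: dict[str, list[str]] = defaultdict(list)
    for i in range(len(s) - m):
        trans[s[i : i + m]].append(s[i + m])
    mono = sorted(set(s))
    out = list(s[:m])
    cur = s[:m]
    for _ in range(len(s) - m):
        choices = trans.get(cur)
        if choices:
            c = choices[int(rng.integers(len(choices)))]
        else:  # absorbing context (only seen at the sequence end): back off
            c = mono[int(rng.integers(len(mono)))]
        out.append(c)
        cur = cur[1:] + c
    return "".join(out)


def shuffle_preserving_klets(
    seq: SequenceLike,
    order: int,
    rng: np.random.Generator | int | None = None,
    method: str = EXACT_KLET,
) -> str:
    """Shuffle a sequence preserving its k-let composition at the given order.

    Sequences containing N are shuffled within their N-free segments, with
    the N positions fixed; segments no longer than the order are left
    unchanged.
    """
    s = as_residues(seq)
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")
    if len(s.replace("N", "")) <= order and "N" not in s:
        raise ValueError(f"sequence of length {len(s)} too short for order {order}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def shuffle_segment(seg: str) -> str:
        if len(seg) <= order:
            return seg
        if method == MARKOV:
            return _markov_shuffle(seg, order, rng)
        if order == 1:
            perm = rng.permutation(len(seg))
            return "".join(seg[i] for i in perm)
        return _eulerian_shuffle(seg, order, rng)

    if "N" not in s:
        return shuffle_segment(s)
    out: list[str] = []
    segment: list[str] = []
    for ch in s:
        if ch == "N":
            if segment:
                out.append(shuffle_segment("".join(segment)))
                segment = []
            out.append("N")
        else:
            segment.append(ch)
    if segment:
        out.append(shuffle_segment("".join(segment)))
    return "".join(out)


def empirical_p(
    replicate_counts: Sequence[float], observed: float, estimator: str = "strict"
) -> float:
    """Fraction of replicates scoring strictly above the observed value.

    Ties count as non-exceedances.  ``estimator="add_one"`` gives the
    (x+1)/(n+1) variant that never returns exactly zero.
    """
    counts = np.asarray(replicate_counts)
    if counts.size == 0:
        raise ValueError("replicate_counts is empty")
    exceed = int(np.sum(counts > observed))
    if estimator == "strict":
        return exceed / counts.size
    if estimator == "add_one":
        return (exceed + 1) / (counts.size + 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def empirical_similarity_null(
    reference: SequenceLike,
    query: SequenceLike,
    k: int,
    statistic: str | Callable[[str, str], int] = similarity.DISTINCT_KMERS,
    config: ShuffleConfig = ShuffleConfig(),
) -> NullDistribution:
    """Empirical null of a similarity statistic under reference shuffling.

    The reference is reshuffled ``config.n_replicates`` times preserving its
    k-let composition; each replicate is scored against the (fixed) query
    with the chosen statistic, and the observed score on the unshuffled
    reference is compared with that distribution.
    """
    ref = as_residues(reference)
    qry = as_residues(query)
    if callable(statistic):
        stat = statistic
    elif statistic == similarity.DISTINCT_KMERS:
        # the query k-mer space is fixed across replicates; hoist it
        query_space = similarity._kmer_set(qry, k) | similarity._kmer_set(
            reverse_complement(qry), k
        )

        def stat(r: str, _q: str) -> int:
            return len(similarity._kmer_set(r, k) & query_space)

    else:
        stat = partial(similarity.count_shared_kmers, k=k, convention=statistic)
    rng = np.random.default_rng(config.seed)
    observed = int(stat(ref, qry))
    counts = []
    for _ in range(config.n_replicates):
        rep = shuffle_preserving_klets(ref, config.order, rng, method=config.method)
        counts.append(int(stat(rep, qry)))
    p = empirical_p(counts, observed)
    return NullDistribution(tuple(counts), observed, p, config)
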