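"""Reporter co-expression quantification and comparison tests.

Each transgenic animal carries a test construct (GFP, driven by an
orthologous cis element) and a control construct (mCherry, driven by the
host's own element).  Per animal and cell class, the data are counts of
GFP-positive and mCherry-positive cells; expression of the test element is
summarised as the ratio of control-positive cells that also express GFP.
Animals without any mCherry signal carry no scoreable transgene and are
excluded.

Comparisons across constructs use the tests standard for such data:
Fisher's exact test on expressing/non-expressing contingency tables,
Kruskal-Wallis across ratio distributions of several constructs, and the
Wilcoxon rank-sum test for pairwise ratio comparisons.  Binomial
proportions carry Wilson score intervals (better small-sample coverage
than Wald; Wald is available for comparison).
"""

from __future__ import annotations

import itertools
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["animal", "construct", "cell_class", "gfp", "mcherry"]


@dataclass
class ReporterCountTable:
    """Per-animal GFP+/mCherry+ cell counts per construct and cell class.

    Wraps a DataFrame with columns animal, construct, cell_class, gfp,
    mcherry and optionally max_cells (the anatomical maximum for the cell
    class).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"count table missing column(s) {missing}")
        df = self.data
        for col in ("gfp", "mcherry"):
            if (df[col] < 0).any():
                raise ValueError(f"negative counts in column {col!r}")
        if "max_cells" in df.columns:
            capped = df["max_cells"].notna()
            over = capped & ((df["gfp"] > df["max_cells"]) | (df["mcherry"] > df["max_cells"]))
            if over.any():
                raise ValueError("cell counts exceed max_cells in some rows")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ReporterCountTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    def ratios(self) -> pd.DataFrame:
        """Per-row GFP/mCherry expression ratios.

        Rows with zero mCherry cells are excluded (mCherry presence is the
        precondition for scoring an animal) and the exclusion is logged.
        """
        df = self.data
        excluded = df["mcherry"] == 0
        if excluded.any():
            logger.info(
                "excluding %d row(s) with zero mCherry-positive cells", int(excluded.sum())
            )
        kept = df.loc[~excluded].copy()
        kept["ratio"] = kept["gfp"] / kept["mcherry"]
        return kept

    def ratio_groups(self, cell_class: str | None = None) -> dict[str, np.ndarray]:
        """Expression-ratio arrays per construct, optionally for one cell class."""
        df = self.ratios()
        if cell_class is not None:
            df = df[df["cell_class"] == cell_class]
        return {c: g["ratio"].to_numpy() for c, g in df.groupby("construct")}


def expression_ratio(gfp_cells: int, mcherry_cells: int) -> float:
    """Fraction of control (mCherry) positive cells that also express GFP."""
    if mcherry_cells <= 0:
        raise ValueError("mcherry_cells must be positive (animal not scoreable)")
    if gfp_cells < 0:
        raise ValueError("negative gfp_cells")
    return gfp_cells / mcherry_cells


def proportion_with_ci(
    expressing: int, total: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float, float]:
    """Binomial proportion with a confidence interval (Wilson score by default)."""
    if not (0 <= expressing <= total):
        raise ValueError("expressing must be in [0, total]")
    if total < 1:
        raise ValueError("total must be >= 1")
    if method not in ("wilson", "wald"):
        raise ValueError(f"unknown CI method {method!r}")
    sm_method = "wilson" if method == "wilson" else "normal"
    low, high = proportion_confint(expressing, total, alpha=1 - level, method=sm_method)
    # the Wilson bound is exactly 0 (resp. 1) at the boundaries; remove
    # floating-point residue
    if expressing == 0:
        low = 0.0
    if expressing == total:
        high = 1.0
    return expressing / total, float(np.clip(low, 0, 1)), float(np.clip(high, 0, 1))


def _validate_2x2(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)) or np.any(arr < 0):
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    return arr


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 contingency table.

    Two-sidedness follows the probability-ordering convention: sum of
    hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one.
    """
    arr = _validate_2x2(table)
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _kw_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H; 0.0 when all observations are equal."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_term == 0.0:
        return 0.0
    return h / tie_term


def kruskal_wallis(groups, method: str = "chi2") -> tuple[float, float]:
    """Kruskal-Wallis test across two or more samples of expression ratios.

    ``method="chi2"`` (default) refers tie-corrected H to the chi-square
    distribution; ``method="exact"`` enumerates all assignments of the
    pooled observations to groups of the observed sizes (total n <= 12)
    and returns the exact permutation p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    h_obs = _kw_h(groups)
    df = len(groups) - 1
    if method == "chi2":
        if h_obs == 0.0:
            return 0.0, 1.0
        return h_obs, float(stats.chi2.sf(h_obs, df))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    if n > 12:
        raise ValueError("exact permutation Kruskal-Wallis limited to total n <= 12")
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n) if n > 1 else 1.0
    indices = list(range(n))
    ge = 0
    total = 0
    # enumerate distinct assignments: choose indices for each group in turn
    def assignments(remaining: list[int], sizes_left: list[int]):
        if len(sizes_left) == 1:
            yield [tuple(remaining)]
            return
        for combo in itertools.combinations(remaining, sizes_left[0]):
            rest = [i for i in remaining if i not in set(combo)]
            for tail in assignments(rest, sizes_left[1:]):
                yield [combo] + tail

    for groups_idx in assignments(indices, sizes):
        h = 0.0
        for gi, size in zip(groups_idx, sizes):
            h += ranks[list(gi)].sum() ** 2 / size
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        h = h / tie_term if tie_term > 0 else 0.0
        total += 1
        if h >= h_obs - 1e-12:
            ge += 1
    return h_obs, ge / total


# exact enumeration is used when the number of rank assignments is modest
EXACT_RANKSUM_LIMIT = 50_000


def rank_sum_test(a, b, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value with tie correction.

    Exact by full enumeration over rank assignments (with midranks, hence
    valid under ties) when C(n+m, n) <= 50000, otherwise the normal
    approximation with tie correction.  The exact two-sided p is the
    fraction of assignments whose rank sum deviates from its mean by at
    least the observed deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    use_exact = method == "exact" or (
        method == "auto" and math.comb(n + m, n) <= EXACT_RANKSUM_LIMIT
    )
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    if not use_exact:
        return float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")[1]
        )
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = 0
    ge = 0
    for combo in itertools.combinations(range(n + m), n):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-12:
            ge += 1
    return ge / total
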