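"""Clonotype-level comparison statistics and 2x2 proportion testing.

The proportion-testing policy is shared by every module: Pearson chi-square
without continuity correction when all expected cell counts reach 5,
otherwise the two-sided Fisher exact test — the standard switch rule for
2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TopShareResult",
    "PublicClonotypeResult",
    "TestResult",
    "TestPolicy",
    "DegenerateTableError",
    "top_n_share",
    "frequency_interval_bins",
    "public_clonotypes",
    "compare_proportions",
    "benjamini_hochberg",
    "venn_counts",
    "DEFAULT_BIN_EDGES",
]

#: log-decade clonotype frequency intervals (the bin upper edges)
DEFAULT_BIN_EDGES = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass
class TopShareResult:
    """Cell share captured by the N most frequent clonotypes of a scope."""

    group: str
    n: int
    cells_in_top_n: int
    total_cells: int
    share: float
    top: pd.DataFrame  # clonotype, count, frequency — ranked

    @property
    def percent(self) -> float:
        return 100.0 * self.share


@dataclass
class PublicClonotypeResult:
    """Clonotypes shared by >= min_samples samples of one group."""

    group: str
    min_samples: int
    keys: list[str]
    presence: pd.DataFrame  # key x sample boolean
    count: int
    percent_of_group_clonotypes: float


@dataclass
class TestResult:
    """One two-group proportion comparison on a 2x2 table."""

    __test__ = False  # not a pytest collectable

    test: str  # pearson_chi2 | fisher_exact
    statistic: float | None
    p_value: float
    table: np.ndarray
    df: int | None


@dataclass(frozen=True)
class TestPolicy:
    """How compare_proportions chooses and runs its test."""

    __test__ = False  # not a pytest collectable

    min_expected: float = 5.0
    yates: bool = False
    force: str | None = None  # force 'pearson_chi2' or 'fisher_exact'


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is zero; no proportion test is defined."""


def top_n_share(counts: pd.Series, n: int, group: str = "") -> TopShareResult:
    """Cell share of the top-``n`` clonotypes of a pooled count vector.

    Ranking is by count descending with ties broken by clonotype key
    ascending, so the boundary is machine-independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = counts[counts > 0]
    if counts.empty:
        raise ValueError("empty clonotype table")
    ranked = counts.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort")
    top = ranked.iloc[:n]
    total = int(counts.sum())
    in_top = int(top.sum())
    return TopShareResult(
        group=group, n=n, cells_in_top_n=in_top, total_cells=total,
        share=in_top / total,
        top=pd.DataFrame({"clonotype": top.index, "count": top.to_numpy(),
                          "frequency": top.to_numpy() / total}))


def frequency_interval_bins(frequencies, edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Histogram of clonotypes per frequency interval.

    Intervals are half-open ``(lo, hi]`` with an implicit leading 0 edge, so
    every clonotype falls in exactly one bin and the bin counts sum to the
    clonotype richness.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) == 0 or (np.diff(edges) <= 0).any():
        raise ValueError("edges must be strictly increasing")
    if not (0 < edges[0] and abs(edges[-1] - 1.0) < 1e-12):
        raise ValueError("edges must lie in (0, 1] and end at 1")
    p = np.asarray(frequencies, dtype=float)
    if len(p) == 0 or (p <= 0).any() or (p > 1).any():
        raise ValueError("frequencies must lie in (0, 1]")
    # searchsorted 'left' maps p in (edges[i-1], edges[i]] to bin i
    idx = np.searchsorted(edges, p, side="left")
    counts = np.bincount(idx, minlength=len(edges))
    lo = np.concatenate([[0.0], edges[:-1]])
    return pd.DataFrame({"bin_low": lo, "bin_high": edges,
                         "n_clonotypes": counts[:len(edges)]})


def public_clonotypes(table, group: str, min_samples: int = 2
                      ) -> PublicClonotypeResult:
    """Clonotypes present in at least ``min_samples`` samples of a group."""
    cols = table.samples_of(group)
    if len(cols) < 2:
        raise ValueError(f"group {group!r} has {len(cols)} sample(s); "
                         "public clonotypes need >= 2")
    if not (2 <= min_samples <= len(cols)):
        raise ValueError(f"min_samples must be in [2, {len(cols)}]")
    present = table.counts[cols] > 0
    group_rows = present.any(axis=1)
    shared = present.sum(axis=1) >= min_samples
    keys = sorted(present.index[shared])
    richness = int(group_rows.sum())
    return PublicClonotypeResult(
        group=group, min_samples=min_samples, keys=keys,
        presence=present.loc[keys], count=len(keys),
        percent_of_group_clonotypes=(100.0 * len(keys) / richness
                                     if richness else 0.0))


def compare_proportions(k1: int, n1: int, k2: int, n2: int,
                        policy: TestPolicy | None = None) -> TestResult:
    """Compare k1/n1 vs k2/n2 on the 2x2 table ``[[k1, n1-k1], [k2, n2-k2]]``.

    Pearson chi-square (df=1, no continuity correction unless
    ``policy.yates``) when every expected count is at least
    ``policy.min_expected``; otherwise the two-sided Fisher exact test (sum
    of hypergeometric point probabilities not exceeding the observed
    table's).
    """
    policy = policy or TestPolicy()
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError(f"invalid counts k={k}, n={n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero margin in table {table.tolist()}")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    use_fisher = (policy.force == "fisher_exact"
                  or (policy.force is None
                      and (expected < policy.min_expected).any()))
    if use_fisher:
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return TestResult("fisher_exact", None, float(p), table, None)
    stat, p, dof, _ = sps.chi2_contingency(table, correction=policy.yates)
    return TestResult("pearson_chi2", float(stat), float(p), table, int(dof))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; comparisons are unadjusted by default)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Region counts of a Venn diagram over named sets.

    Keys are ``"only_<name>"`` for exclusive regions, ``"<a>&<b>"`` (sorted
    names) for every higher-order intersection region, plus ``"union"``.
    """
    names = sorted(sets)
    out: dict[str, int] = {}
    union: set = set().union(*sets.values()) if sets else set()
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            region = inside - outside
            key = f"only_{combo[0]}" if r == 1 else "&".join(combo)
            out[key] = len(region)
    out["union"] = len(union)
    return out
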