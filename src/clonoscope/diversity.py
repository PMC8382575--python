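"""Repertoire diversity, CDR3 spectratyping and V/J gene usage.

Shannon entropy H = -sum p_i ln p_i is reported in natural-log units so the
Hill-number ordering D <= exp(H) holds against the inverse Simpson index
D = 1 / sum p_i^2 (the effective number of dominant clones). Diversity is
computed per sample and compared across groups on the per-sample values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleMeta, TR_LOCI, IG_LOCI
from .stats import TestPolicy, TestResult, compare_proportions, DegenerateTableError

__all__ = [
    "shannon_index",
    "inv_simpson_index",
    "diversity_table",
    "GroupDiversityComparison",
    "compare_group_diversity",
    "cdr3_length_spectrum",
    "gene_usage",
]


def _freqs(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or (c < 0).any():
        raise ValueError("counts must be non-negative and non-empty")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all counts are zero")
    return c / c.sum()


def shannon_index(counts, base: float | None = None) -> float:
    """Shannon–Weiner index of a clone count vector (natural log by default).

    Zero counts are ignored. ``base`` switches the log base (e.g. 2)."""
    p = _freqs(counts)
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base else h


def inv_simpson_index(counts) -> float:
    """Inverse Simpson index 1 / sum p_i^2 (Hill number of order 2)."""
    p = _freqs(counts)
    return float(1.0 / (p ** 2).sum())


def diversity_table(table, log_base: float | None = None) -> pd.DataFrame:
    """Per-sample diversity of a :class:`~clonoscope.clonotypes.ClonotypeTable`.

    One row per sample: group, shannon_H, inv_simpson_D, richness_S, n_cells.
    """
    group_of = {m.sample_id: m.group for m in table.meta}
    rows = []
    for sid in table.sample_ids:
        counts = table.sample_counts(sid)
        if counts.empty:
            continue
        rows.append({
            "sample_id": sid,
            "group": group_of.get(sid, ""),
            "shannon_H": shannon_index(counts, base=log_base),
            "inv_simpson_D": inv_simpson_index(counts),
            "richness_S": int((counts > 0).sum()),
            "n_cells": int(counts.sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class GroupDiversityComparison:
    metric: str
    method: str
    group_means: dict[str, float]
    p_value: float
    n_permutations: int | None = None


def compare_group_diversity(div: pd.DataFrame, metric: str = "inv_simpson",
                            method: str = "welch_t", seed: int = 0,
                            n_perm: int = 10_000) -> GroupDiversityComparison:
    """Compare per-sample diversity between the two groups.

    ``welch_t`` runs the two-sided unequal-variance t-test (needs >= 2
    samples per group); ``permutation`` relabels samples — exhaustively when
    the number of arrangements is at most ``n_perm``, else by seeded Monte
    Carlo with ``n_perm`` draws.
    """
    col = {"shannon": "shannon_H", "inv_simpson": "inv_simpson_D"}[metric]
    groups = list(dict.fromkeys(div["group"]))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    x = div.loc[div["group"] == groups[0], col].to_numpy(dtype=float)
    y = div.loc[div["group"] == groups[1], col].to_numpy(dtype=float)
    means = {groups[0]: float(x.mean()), groups[1]: float(y.mean())}
    if method == "welch_t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("welch_t needs >= 2 samples per group; "
                             "use method='permutation'")
        p = float(sps.ttest_ind(x, y, equal_var=False).pvalue)
        return GroupDiversityComparison(metric, method, means, p)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    obs = abs(x.mean() - y.mean())
    n_arr = math.comb(n, n1)
    if n_arr <= n_perm:
        hits = 0
        for idx in combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            diff = abs(pooled[mask].mean() - pooled[~mask].mean())
            if diff >= obs - 1e-12:
                hits += 1
        return GroupDiversityComparison(metric, method, means, hits / n_arr,
                                        n_permutations=n_arr)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n1].mean() - perm[n1:].mean()) >= obs - 1e-12:
            hits += 1
    # add-one so Monte-Carlo p is never 0
    return GroupDiversityComparison(metric, method, means,
                                    (hits + 1) / (n_perm + 1),
                                    n_permutations=n_perm)


def _receptor_loci(receptor: str) -> tuple[str, ...]:
    return TR_LOCI if receptor == "TCR" else IG_LOCI


def _observations(contigs: pd.DataFrame, meta: list[SampleMeta],
                  receptor: str, unit: str) -> pd.DataFrame:
    """One row per counted chain observation (cell unit or clonotype unit).

    At the cell unit every kept contig of the receptor's loci contributes one
    observation. At the clonotype unit, each distinct per-sample clonotype
    contributes its chains once (one representative barcode per clonotype).
    """
    if unit not in ("cell", "clonotype"):
        raise ValueError(f"unit must be 'cell' or 'clonotype', got {unit!r}")
    sub = contigs[contigs["locus"].isin(_receptor_loci(receptor))]
    if sub.empty:
        raise ValueError(f"no {receptor} contigs in input")
    group_of = {m.sample_id: m.group for m in meta}
    sub = sub.copy()
    sub["group"] = sub["sample_id"].map(group_of)
    if unit == "cell":
        return sub
    chain = (sub["locus"] + ":" + sub["cdr3_nt"].fillna("")).rename("_chain")
    ordered = chain.sort_values(kind="mergesort").groupby(
        sub["barcode"], sort=False).agg(";".join)
    sub = sub.assign(_key=sub["barcode"].map(ordered))
    rep = (sub.groupby(["sample_id", "_key"])["barcode"].transform("min")
           == sub["barcode"])
    return sub[rep].drop(columns="_key")


def _two_group_tests(counts: pd.DataFrame, g1: str, g2: str,
                     policy: TestPolicy | None) -> pd.DataFrame:
    """One-vs-rest 2x2 test per row of a category x group count table."""
    n1, n2 = int(counts[g1].sum()), int(counts[g2].sum())
    rows = []
    for cat, row in counts.iterrows():
        try:
            res = compare_proportions(int(row[g1]), n1, int(row[g2]), n2,
                                      policy=policy)
            rows.append({"test": res.test, "statistic": res.statistic,
                         "p_value": res.p_value})
        except DegenerateTableError:
            rows.append({"test": "none", "statistic": None, "p_value": None})
    return pd.DataFrame(rows, index=counts.index)


def cdr3_length_spectrum(contigs: pd.DataFrame, meta: list[SampleMeta],
                         receptor: str, unit: str = "cell",
                         policy: TestPolicy | None = None) -> pd.DataFrame:
    """CDR3 aa length distribution per group, with a per-length test.

    Every kept chain contributes one observation of its CDR3 amino-acid
    length. Rows are lengths; columns give per-group counts and frequencies
    and a this-length-vs-others proportion test between the two groups.
    """
    obs = _observations(contigs, meta, receptor, unit)
    if obs["cdr3_aa"].isna().any():
        raise ValueError("null cdr3_aa in kept contigs")
    obs = obs.assign(length=obs["cdr3_aa"].str.len().astype(int))
    groups = list(dict.fromkeys(m.group for m in meta))
    counts = (obs.groupby(["length", "group"]).size()
              .unstack(fill_value=0).reindex(columns=groups, fill_value=0))
    counts.columns.name = None
    out = pd.DataFrame(index=counts.index)
    for g in groups:
        out[f"count_{g}"] = counts[g]
        total = counts[g].sum()
        out[f"freq_{g}"] = counts[g] / total if total else 0.0
    if len(groups) == 2:
        tests = _two_group_tests(counts, *groups, policy)
        out = out.join(tests)
    return out.reset_index()


def gene_usage(contigs: pd.DataFrame, meta: list[SampleMeta], segment: str,
               receptor: str, unit: str = "cell",
               policy: TestPolicy | None = None) -> pd.DataFrame:
    """V or J gene usage frequencies per sample and per group, with tests.

    Contigs lacking the gene call are excluded (their number is stored in
    ``df.attrs["n_missing_call"]``). Genes seen in only one group are still
    tested against a zero count in the other. Per-sample frequencies sum to
    1 within each sample.
    """
    if segment not in ("V", "J"):
        raise ValueError("segment must be 'V' or 'J'")
    col = "v_gene" if segment == "V" else "j_gene"
    obs = _observations(contigs, meta, receptor, unit)
    missing = int(obs[col].isna().sum())
    obs = obs[obs[col].notna()]
    if obs.empty:
        raise ValueError(f"no {segment} gene calls for {receptor}")
    groups = list(dict.fromkeys(m.group for m in meta))
    by_group = (obs.groupby([col, "group"]).size()
                .unstack(fill_value=0).reindex(columns=groups, fill_value=0))
    by_group.columns.name = None
    by_sample = (obs.groupby([col, "sample_id"]).size()
                 .unstack(fill_value=0))
    out = pd.DataFrame(index=by_group.index)
    for sid in [m.sample_id for m in meta if m.sample_id in by_sample.columns]:
        total = by_sample[sid].sum()
        out[f"freq_{sid}"] = by_sample[sid] / total if total else 0.0
    for g in groups:
        out[f"count_{g}"] = by_group[g]
        total = by_group[g].sum()
        out[f"freq_{g}"] = by_group[g] / total if total else 0.0
    if len(groups) == 2:
        out = out.join(_two_group_tests(by_group, *groups, policy))
    out = out.reset_index(names="gene")
    out.insert(1, "segment", segment)
    out.attrs["n_missing_call"] = missing
    return out
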