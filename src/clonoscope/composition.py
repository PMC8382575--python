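"""Marker-based cluster labeling and immune-cell composition comparison.

Clusters of a PBMC map are labeled from cluster-level mean expression using
canonical marker panels (CD4 T, CD8 T, B, NK, monocyte–macrophage); a
hemoglobin/platelet panel marks clusters to exclude (ambient contamination).
The composition comparison then tests, per cell type, whether its share of
non-excluded cells differs between the two groups (one-vs-rest 2x2 tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleMeta
from .stats import TestPolicy, compare_proportions, DegenerateTableError

__all__ = ["MarkerMap", "assign_cell_types", "compare_composition"]


def _default_markers() -> dict[str, list[str]]:
    return {
        "CD4_T": ["CD3D", "CD3E", "CD3G", "CD4"],
        "CD8_T": ["CD3D", "CD3E", "CD3G", "CD8A", "CD8B"],
        "B": ["CD19", "CD79A", "CD79B"],
        "NK": ["NKG7", "GZMB", "GNLY", "NCR1"],
        "MonoMac": ["CD14", "CD68"],
    }


@dataclass
class MarkerMap:
    """Canonical marker genes per cell type plus an exclusion panel."""

    markers: dict[str, list[str]] = field(default_factory=_default_markers)
    exclusion_markers: list[str] = field(
        default_factory=lambda: ["HBB", "HBA2", "PF4", "PPBP"])

    def __post_init__(self) -> None:
        for t, genes in self.markers.items():
            if not genes:
                raise ValueError(f"cell type {t!r} has an empty marker list")


def assign_cell_types(expression: pd.DataFrame,
                      markers: MarkerMap | None = None,
                      min_margin: float = 0.1) -> dict[str, str]:
    """Label clusters from a cluster x gene mean-expression matrix.

    Each gene is z-scored across clusters (zero-variance genes contribute
    0); a cluster's score for a type is the mean z over that type's markers,
    and the label is the argmax (ties alphabetical). Clusters whose
    exclusion-panel score beats every type score are ``"excluded"``; a best
    score within ``min_margin`` of the runner-up is ``"unassigned"``.
    """
    if expression.empty:
        raise ValueError("empty expression matrix")
    markers = markers or MarkerMap()
    mu = expression.mean(axis=0)
    sd = expression.std(axis=0, ddof=0)
    z = (expression - mu).div(sd.replace(0.0, np.inf), axis=1)

    def panel_score(genes: list[str]) -> pd.Series:
        present = [g for g in genes if g in z.columns]
        if not present:
            raise ValueError(f"none of the marker genes {genes} are in the matrix")
        if len(present) < len(genes):
            warnings.warn(f"marker genes missing from matrix: "
                          f"{sorted(set(genes) - set(present))}")
        return z[present].mean(axis=1)

    scores = pd.DataFrame({t: panel_score(g) for t, g in
                           sorted(markers.markers.items())})
    excl = panel_score(markers.exclusion_markers)

    out: dict[str, str] = {}
    for cluster in expression.index:
        row = scores.loc[cluster]
        ranked = row.sort_values(ascending=False, kind="mergesort")
        best, second = ranked.iloc[0], (ranked.iloc[1] if len(ranked) > 1
                                        else -np.inf)
        if excl.loc[cluster] > best:
            out[str(cluster)] = "excluded"
        elif best - second < min_margin:
            out[str(cluster)] = "unassigned"
        else:
            # idxmax on the sorted series is alphabetical among exact ties
            tied = ranked.index[ranked == best]
            out[str(cluster)] = str(sorted(tied)[0])
    return out


def compare_composition(annotations: pd.DataFrame, meta: list[SampleMeta],
                        policy: TestPolicy | None = None) -> pd.DataFrame:
    """Per-type cell proportions of each group with one-vs-rest tests.

    Excluded and unassigned cells are removed from the denominators; their
    counts are reported in ``df.attrs["n_removed"]``. Per-group proportions
    over the remaining types sum to 1.
    """
    groups = list(dict.fromkeys(m.group for m in meta))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    group_of = {m.sample_id: m.group for m in meta}
    ann = annotations.assign(group=annotations["sample_id"].map(group_of))
    if ann["group"].isna().any():
        bad = ann.loc[ann["group"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"sample {bad!r} missing from the sample sheet")
    removed = ann["cell_type"].isin(("excluded", "unassigned"))
    n_removed = {g: int((removed & (ann["group"] == g)).sum()) for g in groups}
    ann = ann[~removed]
    for g in groups:
        if not (ann["group"] == g).any():
            raise ValueError(f"group {g!r} has no annotated cells")

    counts = (ann.groupby(["cell_type", "group"]).size()
              .unstack(fill_value=0).reindex(columns=groups, fill_value=0))
    counts.columns.name = None
    totals = {g: int(counts[g].sum()) for g in groups}
    rows = []
    for cell_type, row in counts.iterrows():
        entry = {"cell_type": cell_type}
        for g in groups:
            entry[f"count_{g}"] = int(row[g])
            entry[f"prop_{g}"] = row[g] / totals[g]
        try:
            res = compare_proportions(int(row[groups[0]]), totals[groups[0]],
                                      int(row[groups[1]]), totals[groups[1]],
                                      policy=policy)
            entry.update(test=res.test, statistic=res.statistic,
                         p_value=res.p_value)
        except DegenerateTableError:
            entry.update(test="none", statistic=None, p_value=None)
        rows.append(entry)
    out = pd.DataFrame(rows)
    out.attrs["n_removed"] = n_removed
    return out
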