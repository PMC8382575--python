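"""Clonotype expansion statistics (step 3 of 5).

Compares the two groups on top-10/top-100 clonotype cell shares (with the
chi-square / Fisher proportion test), bins clonotypes into log-decade
frequency intervals, and counts within-group public clonotypes.
Writes top_share_*.tsv, freq_bins_*.tsv, public_clonotypes_*.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from clonoscope import io as rio
from clonoscope.clonotypes import assemble_clonotypes, filter_contigs, \
    clonotype_frequencies
from clonoscope.stats import (compare_proportions, frequency_interval_bins,
                              public_clonotypes, top_n_share, venn_counts)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    meta = rio.read_sample_sheet(DATA / "sample_sheet.tsv")
    groups = list(dict.fromkeys(m.group for m in meta))
    venn_all = {}
    for receptor in ("TCR", "BCR"):
        kept = pd.read_csv(OUT / f"kept_contigs_{receptor}.tsv", sep="\t")
        table = assemble_clonotypes(kept, meta)[receptor]

        rows = []
        shares = {}
        for group in groups:
            counts = table.group_counts(group)
            for n in (10, 100):
                r = top_n_share(counts, n, group=group)
                shares[(group, n)] = r
                rows.append({"group": group, "n": n, "percent": r.percent,
                             "cells_in_top_n": r.cells_in_top_n,
                             "total_cells": r.total_cells})
        for n in (10, 100):
            a, b = shares[(groups[0], n)], shares[(groups[1], n)]
            test = compare_proportions(a.cells_in_top_n, a.total_cells,
                                       b.cells_in_top_n, b.total_cells)
            print(f"{receptor} top-{n}: {groups[0]} {a.percent:.1f}% "
                  f"({a.cells_in_top_n}) vs {groups[1]} {b.percent:.1f}% "
                  f"({b.cells_in_top_n}), {test.test} p={test.p_value:.2e}")
        pd.DataFrame(rows).to_csv(OUT / f"top_share_{receptor}.tsv",
                                  sep="\t", index=False)

        freqs = clonotype_frequencies(table, scope="pooled_group")
        bins = []
        for group in groups:
            b = frequency_interval_bins(
                freqs.loc[freqs["group"] == group, "frequency"])
            b.insert(0, "group", group)
            bins.append(b)
        pd.concat(bins).to_csv(OUT / f"freq_bins_{receptor}.tsv",
                               sep="\t", index=False)

        pubs = []
        for group in groups:
            r = public_clonotypes(table, group, min_samples=2)
            pubs.append({"group": group, "count": r.count,
                         "percent": r.percent_of_group_clonotypes})
            print(f"{receptor} public clonotypes in {group}: {r.count} "
                  f"({r.percent_of_group_clonotypes:.1f}% of group clonotypes)")
        pd.DataFrame(pubs).to_csv(OUT / f"public_clonotypes_{receptor}.tsv",
                                  sep="\t", index=False)
        venn_all[receptor] = venn_counts(
            {g: set(table.group_counts(g).index) for g in groups})
    with open(OUT / "venn_counts.json", "w") as fh:
        json.dump(venn_all, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
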