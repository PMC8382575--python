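"""Diversity, spectratype and V/J usage comparisons (step 4 of 5).

Per-sample Shannon and inverse-Simpson indices with a Welch t group
comparison, the CDR3 amino-acid length spectrum with per-length tests, and
V/J gene usage with per-gene tests. Writes diversity_*.tsv,
spectratype_*.tsv, usage_V_*.tsv, usage_J_*.tsv.
"""

from pathlib import Path

import pandas as pd

from clonoscope import io as rio
from clonoscope.clonotypes import assemble_clonotypes
from clonoscope.diversity import (cdr3_length_spectrum,
                                  compare_group_diversity, diversity_table,
                                  gene_usage)

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    meta = rio.read_sample_sheet(DATA / "sample_sheet.tsv")
    for receptor in ("TCR", "BCR"):
        kept = pd.read_csv(OUT / f"kept_contigs_{receptor}.tsv", sep="\t")
        table = assemble_clonotypes(kept, meta)[receptor]

        div = diversity_table(table)
        div.to_csv(OUT / f"diversity_{receptor}.tsv", sep="\t", index=False)
        for metric in ("inv_simpson", "shannon"):
            cmp_ = compare_group_diversity(div, metric=metric)
            means = ", ".join(f"{g} {v:.2f}" for g, v in cmp_.group_means.items())
            print(f"{receptor} {metric}: {means} (Welch p={cmp_.p_value:.3g})")

        spec = cdr3_length_spectrum(kept, meta, receptor)
        spec.to_csv(OUT / f"spectratype_{receptor}.tsv", sep="\t", index=False)
        groups = list(dict.fromkeys(m.group for m in meta))
        modal = {g: int(spec.loc[spec[f"freq_{g}"].idxmax(), "length"])
                 for g in groups}
        sig = spec.loc[spec["p_value"] < 0.05, "length"].tolist()
        print(f"{receptor} modal CDR3 length {modal}; "
              f"lengths with p<0.05: {sig or 'none'}")

        for seg in ("V", "J"):
            usage = gene_usage(kept, meta, seg, receptor)
            usage.to_csv(OUT / f"usage_{seg}_{receptor}.tsv", sep="\t",
                         index=False)
            n_sig = int((usage["p_value"] < 0.05).sum())
            print(f"{receptor} {seg}-gene usage: {len(usage)} genes, "
                  f"{n_sig} with p<0.05")


if __name__ == "__main__":
    main()
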