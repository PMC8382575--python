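"""Generate the synthetic study dataset (step 1 of 5).

Emulates the study design: two groups (AD, NC) with 3 and 2 samples, one
TCR and one BCR repertoire per sample, plus per-cell type annotations.
Disease samples carry an expanded-clone mass of 0.15; controls none.
Writes 10x-style contig CSVs, a sample sheet, annotations and the generator
ground truth under results/data/.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import json
import sys
from pathlib import Path

from clonoscope import io as rio
from clonoscope.simulate import (SyntheticConfig, simulate_cell_annotations,
                                 simulate_repertoire)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for receptor in ("TCR", "BCR"):
        config = SyntheticConfig(receptor=receptor, seed=SEED)
        contigs, meta, truth = simulate_repertoire(config)
        for m in meta:
            path = OUT / f"{m.sample_id}_{receptor}_contigs.csv"
            rio.write_contig_table(contigs[contigs["sample_id"] == m.sample_id], path)
        truth.clone_table.to_csv(OUT / f"truth_clones_{receptor}.tsv",
                                 sep="\t", index=False)
        manifest[receptor] = {
            "contigs": int(len(contigs)),
            "samples": [m.sample_id for m in meta],
            "expanded_clones": len(truth.expanded_clone_ids),
        }
        print(f"{receptor}: {len(contigs)} contigs over {len(meta)} samples "
              f"({len(truth.expanded_clone_ids)} expanded clones per group pool)")

    config = SyntheticConfig(seed=SEED)
    ann = simulate_cell_annotations(config)
    ann.to_csv(OUT / "cell_annotations.tsv", sep="\t", index=False)
    with open(OUT / "sample_sheet.tsv", "w") as fh:
        fh.write("sample_id\tgroup\treceptor\n")
        for sid, group in config.sample_ids():
            fh.write(f"{sid}\t{group}\tboth\n")
    manifest["annotations"] = int(len(ann))
    manifest["seed"] = SEED
    with open(OUT / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    print(f"annotations: {len(ann)} cells; dataset in {OUT}/")


if __name__ == "__main__":
    main()
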