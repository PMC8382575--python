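"""QC filtering of contigs and clonotype assembly.

A *clonotype* is the canonical sorted set of (locus, CDR3) pairs over a
cell's kept contigs — nucleotide-level CDR3 by default (the convention of
the upstream 10x pipeline), amino-acid level by flag. Counts are cells
(barcodes), so clonotype frequencies are cell shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleMeta, TR_LOCI, IG_LOCI

__all__ = [
    "QCConfig",
    "ClonotypeTable",
    "filter_contigs",
    "assemble_clonotypes",
    "clonotype_frequencies",
    "read_clonotype_table",
]


@dataclass(frozen=True)
class QCConfig:
    """Which flags a contig must carry to be kept (Cell Ranger semantics)."""

    require_is_cell: bool = True
    require_high_confidence: bool = True
    require_full_length: bool = True
    require_productive: bool = True
    require_cdr3_nt: bool = True
    drop_cross_lineage: bool = True


def filter_contigs(contigs: pd.DataFrame, qc: QCConfig | None = None
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply QC to a contig table.

    Keep rules, in order:

    1. flag filter — ``is_cell & high_confidence & full_length & productive``
       and a non-null ``cdr3_nt`` (each independently switchable);
    2. cross-lineage doublets — barcodes that still carry both TR and IG
       contigs are dropped entirely;
    3. within each (barcode, locus) only the best-supported contig survives
       (highest UMIs, then highest reads, then lexicographically smallest
       ``raw_contig_id``).

    Returns the kept rows (original order preserved) and a QC report counting
    removals per rule. Idempotent: filtering a filtered table is a no-op.
    """
    qc = qc or QCConfig()
    report: dict[str, int] = {}
    df = contigs

    keep = pd.Series(True, index=df.index)
    for flag, required in (("is_cell", qc.require_is_cell),
                           ("high_confidence", qc.require_high_confidence),
                           ("full_length", qc.require_full_length),
                           ("productive", qc.require_productive)):
        if required:
            fail = keep & ~df[flag].astype(bool)
            report[f"not_{flag}"] = int(fail.sum())
            keep &= ~fail
    if qc.require_cdr3_nt:
        fail = keep & df["cdr3_nt"].isna()
        report["missing_cdr3_nt"] = int(fail.sum())
        keep &= ~fail
    df = df[keep]

    if qc.drop_cross_lineage and len(df):
        is_tr = df["locus"].isin(TR_LOCI)
        by_bc = is_tr.groupby(df["barcode"]).agg(["any", "all"])
        mixed = by_bc.index[by_bc["any"] & ~by_bc["all"]]
        report["cross_lineage_dropped"] = int(len(mixed))
        df = df[~df["barcode"].isin(mixed)]
    else:
        report["cross_lineage_dropped"] = 0

    if len(df):
        order = df.sort_values(
            ["barcode", "locus", "umis", "reads", "raw_contig_id"],
            ascending=[True, True, False, False, True], kind="mergesort")
        best = order.drop_duplicates(subset=["barcode", "locus"], keep="first")
        report["multi_chain_dropped"] = int(len(df) - len(best))
        df = df.loc[df.index.isin(best.index)]
    else:
        report["multi_chain_dropped"] = 0
    return df, report


@dataclass
class ClonotypeTable:
    """Clonotype -> per-sample cell counts for one receptor.

    ``counts`` is a DataFrame indexed by the canonical clonotype key string
    (``"LOCUS:CDR3;LOCUS:CDR3"``), one integer column per sample.
    """

    receptor: str
    key_level: str
    counts: pd.DataFrame
    meta: list[SampleMeta] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> pd.Series:
        """Cells per sample."""
        return self.counts.sum(axis=0)

    @property
    def richness(self) -> pd.Series:
        """Distinct clonotypes per sample."""
        return (self.counts > 0).sum(axis=0)

    @property
    def pooled_richness(self) -> int:
        return int((self.counts.sum(axis=1) > 0).sum())

    def samples_of(self, group: str) -> list[str]:
        return [m.sample_id for m in self.meta
                if m.group == group and m.sample_id in self.counts.columns]

    def group_counts(self, group: str) -> pd.Series:
        """Pooled cell counts over the group's samples (zero rows dropped)."""
        cols = self.samples_of(group)
        if not cols:
            raise ValueError(f"no samples for group {group!r}")
        pooled = self.counts[cols].sum(axis=1)
        return pooled[pooled > 0]

    def sample_counts(self, sample_id: str) -> pd.Series:
        s = self.counts[sample_id]
        return s[s > 0]

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready view: key, receptor, per-sample counts, pooled."""
        out = self.counts.reset_index(names="clonotype")
        out.insert(1, "receptor", self.receptor)
        out["pooled_count"] = self.counts.sum(axis=1).to_numpy()
        out["pooled_frequency"] = out["pooled_count"] / out["pooled_count"].sum()
        return out


def read_clonotype_table(path, meta: list[SampleMeta],
                         key_level: str = "nt") -> ClonotypeTable:
    """Read back a clonotype TSV written by :meth:`ClonotypeTable.to_frame`.

    Supports workflows that start from an exported per-clonotype table
    rather than per-contig annotations.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"clonotype", "receptor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clonotype table missing column(s) {sorted(missing)}")
    receptors = df["receptor"].unique()
    if len(receptors) != 1:
        raise ValueError(f"expected one receptor per table, got {list(receptors)}")
    sample_cols = [m.sample_id for m in meta if m.sample_id in df.columns]
    if not sample_cols:
        raise ValueError("no sample columns match the sample sheet")
    counts = df.set_index("clonotype")[sample_cols].astype(int).sort_index()
    counts.index.name = "clonotype"
    return ClonotypeTable(receptor=str(receptors[0]), key_level=key_level,
                          counts=counts, meta=list(meta))


def _receptor_of(locus: str) -> str:
    return "TCR" if locus.startswith("TR") else "BCR"


def assemble_clonotypes(contigs: pd.DataFrame, meta: list[SampleMeta],
                        key_level: str = "nt") -> dict[str, ClonotypeTable]:
    """Group kept contigs per barcode into clonotypes.

    Returns a dict with a :class:`ClonotypeTable` per receptor present
    (``"TCR"`` from TRA/TRB contigs, ``"BCR"`` from IGH/IGK/IGL). Inputs must
    be pre-filtered; a barcode mixing TR and IG loci raises.
    """
    if key_level not in ("nt", "aa"):
        raise ValueError(f"key_level must be 'nt' or 'aa', got {key_level!r}")
    out: dict[str, ClonotypeTable] = {}
    if contigs.empty:
        return out
    col = "cdr3_nt" if key_level == "nt" else "cdr3_aa"
    if contigs[col].isna().any():
        raise ValueError(f"null {col} in kept contigs; run filter_contigs first")

    df = contigs[["barcode", "sample_id", "locus", col]].copy()
    df["receptor"] = df["locus"].map(_receptor_of)
    mixed = df.groupby("barcode")["receptor"].nunique()
    if (mixed > 1).any():
        bad = mixed.index[(mixed > 1).to_numpy()][0]
        raise ValueError(
            f"barcode {bad!r} mixes TR and IG contigs; filter_contigs must "
            "remove cross-lineage doublets first")

    df["chain"] = df["locus"] + ":" + df[col]
    df = df.sort_values(["barcode", "chain"], kind="mergesort")
    per_cell = (df.groupby(["receptor", "sample_id", "barcode"], sort=False)
                ["chain"].agg(";".join).reset_index(name="clonotype"))

    sample_ids = [m.sample_id for m in meta]
    for receptor, sub in per_cell.groupby("receptor"):
        table = (sub.groupby(["clonotype", "sample_id"]).size()
                 .unstack(fill_value=0))
        table = table.reindex(columns=[s for s in sample_ids],
                              fill_value=0).sort_index()
        table.columns.name = None
        table.index.name = "clonotype"
        out[receptor] = ClonotypeTable(receptor=receptor, key_level=key_level,
                                       counts=table, meta=list(meta))
    return out


def clonotype_frequencies(table: ClonotypeTable, scope: str = "pooled_group",
                          ) -> pd.DataFrame:
    """Clonotype cell-share frequencies, per sample or pooled per group.

    Returns a tidy frame (clonotype, scope unit, count, frequency); within
    every scope unit the frequencies sum to 1.
    """
    rows = []
    if scope == "per_sample":
        for sid in table.sample_ids:
            counts = table.sample_counts(sid)
            if counts.empty:
                raise ValueError(f"sample {sid!r}: no clonotypes")
            rows.append(pd.DataFrame({
                "clonotype": counts.index, "sample_id": sid,
                "count": counts.to_numpy(),
                "frequency": counts.to_numpy() / counts.sum()}))
    elif scope == "pooled_group":
        groups = list(dict.fromkeys(m.group for m in table.meta))
        for g in groups:
            counts = table.group_counts(g)
            if counts.empty:
                raise ValueError(f"group {g!r}: no clonotypes")
            rows.append(pd.DataFrame({
                "clonotype": counts.index, "group": g,
                "count": counts.to_numpy(),
                "frequency": counts.to_numpy() / counts.sum()}))
    else:
        raise ValueError(f"scope must be 'per_sample' or 'pooled_group', got {scope!r}")
    return pd.concat(rows, ignore_index=True)
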