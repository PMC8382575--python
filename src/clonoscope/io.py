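"""Tabular input/output for the repertoire pipeline.

Contigs are carried in memory as a :class:`pandas.DataFrame` with the fixed
column schema :data:`CONTIG_COLUMNS` — one row per assembled V(D)J contig of
one cell barcode. Readers validate strictly (schema errors name the missing
column, row-level errors name the row) and prefix barcodes with the sample id
so that pooling samples within a group can never collide barcodes.

Two input dialects are built in:

``10x``
    Cell Ranger ``filtered_contig_annotations.csv`` column names (default).
``airr``
    AIRR Rearrangement TSV names (``cell_id``, ``v_call``, ``junction_aa`` …);
    columns the AIRR schema lacks (``high_confidence``, ``full_length``,
    ``is_cell``) default to true with a warning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CONTIG_COLUMNS",
    "LOCI",
    "TR_LOCI",
    "IG_LOCI",
    "Dialect",
    "DIALECTS",
    "SchemaError",
    "RowError",
    "SampleMeta",
    "read_contig_table",
    "write_contig_table",
    "read_cell_annotations",
    "read_sample_sheet",
    "write_results",
]

#: canonical in-memory contig schema (column -> dtype kind)
CONTIG_COLUMNS = {
    "barcode": "str",
    "sample_id": "str",
    "locus": "str",
    "v_gene": "str?",
    "d_gene": "str?",
    "j_gene": "str?",
    "c_gene": "str?",
    "cdr3_aa": "str?",
    "cdr3_nt": "str?",
    "umis": "int",
    "reads": "int",
    "productive": "bool",
    "high_confidence": "bool",
    "full_length": "bool",
    "is_cell": "bool",
    "raw_contig_id": "str",
}

TR_LOCI = ("TRA", "TRB")
IG_LOCI = ("IGH", "IGK", "IGL")
LOCI = TR_LOCI + IG_LOCI

CELL_TYPES = ("CD4_T", "CD8_T", "B", "NK", "MonoMac", "excluded", "unassigned")

_BOOL_MAP = {"true": True, "false": False}
_NULL_GENE = {"", "none", "nan", "na"}


class SchemaError(ValueError):
    """A required column is missing or mis-named."""


class RowError(ValueError):
    """A data row cannot be parsed; the message carries the row number."""


@dataclass(frozen=True)
class Dialect:
    """Mapping from on-disk column names to the canonical contig schema."""

    name: str
    sep: str
    #: canonical name -> file column name
    columns: dict[str, str]
    #: canonical boolean columns absent from the file, filled with True
    default_true: tuple[str, ...] = ()

    def required(self) -> list[str]:
        return [v for v in self.columns.values()]


DIALECTS: dict[str, Dialect] = {
    "10x": Dialect(
        name="10x",
        sep=",",
        columns={
            "barcode": "barcode",
            "locus": "chain",
            "v_gene": "v_gene",
            "d_gene": "d_gene",
            "j_gene": "j_gene",
            "c_gene": "c_gene",
            "cdr3_aa": "cdr3",
            "cdr3_nt": "cdr3_nt",
            "umis": "umis",
            "reads": "reads",
            "productive": "productive",
            "high_confidence": "high_confidence",
            "full_length": "full_length",
            "is_cell": "is_cell",
            "raw_contig_id": "contig_id",
        },
    ),
    "airr": Dialect(
        name="airr",
        sep="\t",
        columns={
            "barcode": "cell_id",
            "locus": "locus",
            "v_gene": "v_call",
            "d_gene": "d_call",
            "j_gene": "j_call",
            "c_gene": "c_call",
            "cdr3_aa": "junction_aa",
            "cdr3_nt": "junction",
            "umis": "duplicate_count",
            "reads": "consensus_count",
            "productive": "productive",
            "raw_contig_id": "sequence_id",
        },
        default_true=("high_confidence", "full_length", "is_cell"),
    ),
}


@dataclass(frozen=True)
class SampleMeta:
    """One sample-sheet row: sample id, group label and receptor content."""

    sample_id: str
    group: str
    receptor: str = "both"  # TCR | BCR | both


def _parse_bool_column(raw: pd.Series, colname: str) -> pd.Series:
    s = raw.astype(str).str.strip().str.lower()
    bad = ~s.isin(_BOOL_MAP)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(
            f"column {colname!r}, data row {row + 1}: "
            f"unparseable boolean {raw.iloc[row]!r} (expected True/False)"
        )
    return s.map(_BOOL_MAP)


def _parse_int_column(raw: pd.Series, colname: str) -> pd.Series:
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() | (out % 1 != 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(
            f"column {colname!r}, data row {row + 1}: "
            f"unparseable integer {raw.iloc[row]!r}"
        )
    return out.astype(np.int64)


def _normalize_gene(raw: pd.Series) -> pd.Series:
    s = raw.astype(str).str.strip()
    return s.mask(s.str.lower().isin(_NULL_GENE), other=None)


def read_contig_table(
    path: str | Path,
    sample_id: str,
    dialect: str | Dialect = "10x",
) -> pd.DataFrame:
    """Read one per-contig annotation table into the canonical schema.

    Parameters
    ----------
    path
        CSV/TSV file in the given dialect.
    sample_id
        Prefixed onto every barcode (``"{sample_id}_{barcode}"``) and stored
        in the ``sample_id`` column.
    dialect
        ``"10x"`` (default), ``"airr"``, or a custom :class:`Dialect`.

    Returns
    -------
    DataFrame with :data:`CONTIG_COLUMNS`, one row per data row of the file,
    in file order. The frame carries a ``warnings`` entry in ``df.attrs``
    counting defaulted columns.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}")
    path = Path(path)
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)

    missing = [c for c in dialect.required() if c not in raw.columns]
    # is_cell may legitimately be absent from processed exports
    file_is_cell = dialect.columns.get("is_cell")
    warnings: list[str] = []
    if file_is_cell is not None and file_is_cell in missing:
        missing.remove(file_is_cell)
        warnings.append(f"missing column {file_is_cell!r}: is_cell defaulted to True")
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing} for dialect {dialect.name!r}"
        )

    out = pd.DataFrame(index=raw.index)
    out["barcode"] = sample_id + "_" + raw[dialect.columns["barcode"]].astype(str)
    out["sample_id"] = sample_id

    locus = raw[dialect.columns["locus"]].astype(str).str.strip()
    bad_locus = ~locus.isin(LOCI)
    if bad_locus.any():
        row = int(np.flatnonzero(bad_locus.to_numpy())[0])
        raise RowError(
            f"data row {row + 1}: unknown locus {locus.iloc[row]!r}; "
            f"allowed values: {list(LOCI)}"
        )
    out["locus"] = locus

    for canon in ("v_gene", "d_gene", "j_gene", "c_gene", "cdr3_aa", "cdr3_nt"):
        out[canon] = _normalize_gene(raw[dialect.columns[canon]])
    for canon in ("umis", "reads"):
        out[canon] = _parse_int_column(raw[dialect.columns[canon]], dialect.columns[canon])
    for canon in ("productive", "high_confidence", "full_length", "is_cell"):
        file_col = dialect.columns.get(canon)
        if file_col is not None and file_col in raw.columns:
            out[canon] = _parse_bool_column(raw[file_col], file_col)
        else:
            out[canon] = True
            if canon in dialect.default_true:
                warnings.append(f"{canon} not in {dialect.name!r} dialect: defaulted to True")
            elif not any("is_cell defaulted" in w for w in warnings):
                warnings.append(f"column for {canon!r} absent: defaulted to True")
    out["raw_contig_id"] = raw[dialect.columns["raw_contig_id"]].astype(str)

    _validate_contigs(out)
    out = out[list(CONTIG_COLUMNS)]
    out.attrs["warnings"] = warnings
    return out


def _validate_contigs(df: pd.DataFrame) -> None:
    if (df["umis"] < 0).any():
        row = int(np.flatnonzero((df["umis"] < 0).to_numpy())[0])
        raise RowError(f"data row {row + 1}: negative umis")
    bad = df["reads"] < df["umis"]
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(f"data row {row + 1}: reads < umis")
    nt = df["cdr3_nt"].dropna()
    if len(nt) and not nt.str.fullmatch("[ACGT]+").all():
        bad_idx = nt.index[~nt.str.fullmatch("[ACGT]+")][0]
        raise RowError(f"data row {bad_idx + 1}: cdr3_nt is not an ACGT string")


def write_contig_table(
    df: pd.DataFrame, path: str | Path, dialect: str | Dialect = "10x"
) -> None:
    """Write contigs back to disk in the given dialect (inverse of the reader).

    The sample prefix is stripped from barcodes so a read→write round trip
    reproduces the input file modulo whitespace/caseless-boolean normalization.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    out = pd.DataFrame(index=df.index)
    for canon, file_col in dialect.columns.items():
        if canon == "barcode":
            prefix = df["sample_id"].astype(str) + "_"
            stripped = [
                b[len(p):] if b.startswith(p) else b
                for b, p in zip(df["barcode"], prefix)
            ]
            out[file_col] = stripped
        elif canon in ("productive", "high_confidence", "full_length", "is_cell"):
            out[file_col] = df[canon].map({True: "True", False: "False"})
        elif canon in ("v_gene", "d_gene", "j_gene", "c_gene", "cdr3_aa", "cdr3_nt"):
            out[file_col] = df[canon].fillna("None")
        else:
            out[file_col] = df[canon]
    out.to_csv(path, sep=dialect.sep, index=False)


def read_cell_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-cell annotations (barcode, sample_id, cluster, cell_type).

    Accepts TSV or CSV (sniffed from the header line). Unknown ``cell_type``
    strings are mapped to ``"unassigned"``; the count of such rows is stored
    in ``df.attrs["n_unknown_cell_type"]``.

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValueError
        on a duplicated (barcode, sample_id) pair, reporting the first.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = ["barcode", "sample_id", "cluster", "cell_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    df = df[required].copy()
    dup = df.duplicated(subset=["barcode", "sample_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate cell annotation for barcode={row['barcode']!r} "
            f"sample_id={row['sample_id']!r}"
        )
    unknown = ~df["cell_type"].isin(CELL_TYPES)
    df.loc[unknown, "cell_type"] = "unassigned"
    df.attrs["n_unknown_cell_type"] = int(unknown.sum())
    return df


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the sample sheet (sample_id, group[, receptor]) as a TSV/CSV."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in ("sample_id", "group") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("sample sheet: duplicated sample_id")
    receptor = df["receptor"] if "receptor" in df.columns else ["both"] * len(df)
    return [
        SampleMeta(sample_id=s, group=g, receptor=r)
        for s, g, r in zip(df["sample_id"], df["group"], receptor)
    ]


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def write_results(bundle: dict[str, pd.DataFrame], out_dir: str | Path,
                  summary: dict | None = None) -> dict:
    """Write a bundle of result tables as TSVs plus one ``summary.json``.

    Float columns are serialized with 6 significant digits; column order is
    preserved as given, so writing the same bundle twice is byte-identical.

    Returns the manifest: ``{"files": {name: row_count}, "summary": path}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "summary": "summary.json"}
    for name in sorted(bundle):
        fname = f"{name}.tsv"
        bundle[name].to_csv(out_dir / fname, sep="\t", index=False,
                            float_format="%.6g")
        manifest["files"][fname] = int(len(bundle[name]))
    payload = {"tables": manifest["files"]}
    if summary:
        payload.update(_jsonify(summary))
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def _jsonify(obj):
    """Recursively convert numpy scalars and round floats for stable JSON."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    return obj
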