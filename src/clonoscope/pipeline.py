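"""End-to-end orchestration: read → QC → assemble → compare → write.

The pipeline adds no computation of its own — every number it writes is
reproducible by calling the module functions directly — and is fully
deterministic for a fixed config and seed. A ``manifest.json`` records the
config hash, seed, per-stage row counts and warnings; a failed stage leaves
a ``FAILED`` marker in the manifest and raises.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as rio
from .clonotypes import QCConfig, assemble_clonotypes, clonotype_frequencies, filter_contigs
from .composition import compare_composition
from .diversity import (cdr3_length_spectrum, compare_group_diversity,
                        diversity_table, gene_usage)
from .stats import (DEFAULT_BIN_EDGES, TestPolicy, frequency_interval_bins,
                    public_clonotypes, top_n_share, venn_counts)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :meth:`from_yaml`."""

    contig_tables: list[dict] = field(default_factory=list)  # path/sample_id/dialect
    sample_sheet: str | None = None
    annotations: str | None = None
    out_dir: str = "clonoscope_out"
    receptors: list[str] = field(default_factory=lambda: ["TCR", "BCR"])
    key_level: str = "nt"
    top_n: list[int] = field(default_factory=lambda: [10, 100])
    bin_edges: list[float] = field(default_factory=lambda: list(DEFAULT_BIN_EDGES))
    min_samples: int = 2
    unit: str = "cell"
    log_base: float | None = None
    diversity_method: str = "welch_t"
    min_margin: float = 0.1
    yates: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        # out_dir is excluded: it does not affect any computed number
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed,
                      "stages": {}, "warnings": []}
    bundle: dict[str, pd.DataFrame] = {}
    summary: dict = {}
    policy = TestPolicy(yates=config.yates)
    stage = "read"
    try:
        if not config.contig_tables:
            raise ValueError("no contig tables configured")
        if config.sample_sheet is None:
            raise ValueError("no sample sheet configured")
        meta = rio.read_sample_sheet(config.sample_sheet)
        frames = []
        for entry in config.contig_tables:
            df = rio.read_contig_table(entry["path"], entry["sample_id"],
                                       dialect=entry.get("dialect", "10x"))
            manifest["warnings"] += df.attrs.get("warnings", [])
            frames.append(df)
        contigs = pd.concat(frames, ignore_index=True)
        manifest["stages"]["read"] = {"rows": int(len(contigs)), "status": "ok"}

        stage = "filter"
        kept, qc_report = filter_contigs(contigs, QCConfig())
        summary["qc"] = qc_report
        manifest["stages"]["filter"] = {"rows": int(len(kept)), "status": "ok"}

        stage = "assemble"
        tables = assemble_clonotypes(kept, meta, key_level=config.key_level)
        manifest["stages"]["assemble"] = {
            "rows": int(sum(len(t.counts) for t in tables.values())),
            "status": "ok"}

        groups = list(dict.fromkeys(m.group for m in meta))
        for receptor in config.receptors:
            if receptor not in tables:
                raise ValueError(f"no {receptor} clonotypes after filtering")
            table = tables[receptor]
            bundle[f"clonotypes_{receptor}"] = table.to_frame()
            rsum: dict = {}

            stage = f"top_share[{receptor}]"
            shares = []
            for g in groups:
                counts = table.group_counts(g)
                for n in config.top_n:
                    r = top_n_share(counts, n, group=g)
                    shares.append({"group": g, "n": n, "share": r.share,
                                   "percent": r.percent,
                                   "cells_in_top_n": r.cells_in_top_n,
                                   "total_cells": r.total_cells})
            bundle[f"top_share_{receptor}"] = pd.DataFrame(shares)
            rsum["top_share"] = shares

            stage = f"freq_bins[{receptor}]"
            bins = []
            freqs = clonotype_frequencies(table, scope="pooled_group")
            for g in groups:
                b = frequency_interval_bins(
                    freqs.loc[freqs["group"] == g, "frequency"],
                    config.bin_edges)
                b.insert(0, "group", g)
                bins.append(b)
            bundle[f"freq_bins_{receptor}"] = pd.concat(bins, ignore_index=True)

            stage = f"public[{receptor}]"
            pubs, sets = [], {}
            for g in groups:
                if len(table.samples_of(g)) >= 2:
                    r = public_clonotypes(table, g, config.min_samples)
                    pubs.append({"group": g, "min_samples": r.min_samples,
                                 "count": r.count,
                                 "percent_of_group_clonotypes":
                                     r.percent_of_group_clonotypes})
                sets[g] = set(table.group_counts(g).index)
            bundle[f"public_clonotypes_{receptor}"] = pd.DataFrame(pubs)
            rsum["public_clonotypes"] = pubs
            rsum["group_venn"] = venn_counts(sets)

            stage = f"diversity[{receptor}]"
            div = diversity_table(table, log_base=config.log_base)
            bundle[f"diversity_{receptor}"] = div
            rsum["diversity"] = {}
            for metric in ("shannon", "inv_simpson"):
                cmp_ = compare_group_diversity(
                    div, metric=metric, method=config.diversity_method,
                    seed=config.seed)
                rsum["diversity"][metric] = {
                    "group_means": cmp_.group_means, "p_value": cmp_.p_value,
                    "method": cmp_.method}

            stage = f"spectratype[{receptor}]"
            bundle[f"spectratype_{receptor}"] = cdr3_length_spectrum(
                kept, meta, receptor, unit=config.unit, policy=policy)

            stage = f"usage[{receptor}]"
            for seg in ("V", "J"):
                usage = gene_usage(kept, meta, seg, receptor,
                                   unit=config.unit, policy=policy)
                bundle[f"usage_{seg}_{receptor}"] = usage
            summary[receptor] = rsum

        if config.annotations:
            stage = "composition"
            ann = rio.read_cell_annotations(config.annotations)
            if ann.attrs.get("n_unknown_cell_type"):
                manifest["warnings"].append(
                    f"{ann.attrs['n_unknown_cell_type']} cells with unknown "
                    "cell_type mapped to 'unassigned'")
            comp = compare_composition(ann, meta, policy=policy)
            bundle["composition"] = comp
            summary["composition"] = {
                "n_removed": comp.attrs["n_removed"],
                "rows": comp.to_dict(orient="records")}

        stage = "write"
        written = rio.write_results(bundle, out_dir, summary=summary)
        for name, rows in written["files"].items():
            manifest["stages"][f"write[{name}]"] = {"rows": rows, "status": "ok"}
    except Exception as exc:
        manifest["stages"][stage] = {"status": "FAILED", "error": str(exc)}
        _write_manifest(manifest, out_dir)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
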