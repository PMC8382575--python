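"""Synthetic paired-chain V(D)J repertoire generator.

Emulates 10x-style single-cell TCR/BCR data for a two-group study design
(by default 3 disease vs 2 control samples) with the statistical structure
the downstream comparisons assume:

* a heavy-tailed background clone-size law — per sample, background clone
  weights are a symmetric Dirichlet draw over a group-shared clone pool;
* a controllable *expanded-clone* component: a fraction ``expansion_mass``
  (phi) of the cell mass is concentrated on ``n_expanded_clones`` clones,
  the one knob that produces oligoclonal expansion and depressed diversity;
* group-tilted V/J gene usage (group probabilities proportional to
  ``base**(1/tau)``);
* CDR3 amino-acid lengths drawn per clone from a peaked length law
  (discretized Gaussian, mode 14 aa for TCR, 12 aa for BCR);
* contig-level noise (non-productive and low-confidence contigs, same-locus
  doublet barcodes).

Every clone carries a fixed paired-chain identity (TRA+TRB, or IGH plus one
light chain), so the generator's clone partition is exactly recoverable by
clonotype assembly on noise-free output; the returned
:class:`SyntheticTruth` carries everything recovery tests need.

All randomness flows from one seeded :class:`numpy.random.Generator`; there
is no global random state and a fixed seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import SampleMeta, TR_LOCI, IG_LOCI

__all__ = [
    "ConfigError",
    "NoiseConfig",
    "GroupSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_repertoire",
    "simulate_cell_annotations",
    "default_length_law",
    "default_vj_usage",
    "default_composition",
    "GENE_POOLS",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


# standard-code codons per amino acid (no stops); used for codon-uniform
# back-translation of CDR3 aa sequences
AA_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}
AA_ALPHABET = "".join(sorted(AA_CODONS))  # 20 letters, fixed order
_AA_NCODON = np.array([len(AA_CODONS[a]) for a in AA_ALPHABET])
_CODON_LOOKUP = np.array(
    [[AA_CODONS[a][i % len(AA_CODONS[a])] for i in range(6)] for a in AA_ALPHABET]
)

# Germline segment pools per locus. Subsets of common human segments — enough
# names for realistic usage tables; no germline sequence modelling is done.
GENE_POOLS: dict[str, dict[str, tuple[str, ...]]] = {
    "TRA": {
        "V": ("TRAV1-2", "TRAV8-2", "TRAV12-1", "TRAV13-1", "TRAV17",
              "TRAV19", "TRAV21", "TRAV26-1", "TRAV29DV5", "TRAV38-1"),
        "J": ("TRAJ6", "TRAJ23", "TRAJ30", "TRAJ33", "TRAJ42", "TRAJ45",
              "TRAJ49", "TRAJ54"),
    },
    "TRB": {
        "V": ("TRBV2", "TRBV5-1", "TRBV6-5", "TRBV7-2", "TRBV7-9", "TRBV9",
              "TRBV12-3", "TRBV19", "TRBV20-1", "TRBV28", "TRBV29-1",
              "TRBV30"),
        "J": ("TRBJ1-1", "TRBJ1-2", "TRBJ1-5", "TRBJ2-1", "TRBJ2-2",
              "TRBJ2-3", "TRBJ2-5", "TRBJ2-7"),
    },
    "IGH": {
        "V": ("IGHV1-2", "IGHV1-69", "IGHV3-7", "IGHV3-23", "IGHV3-30",
              "IGHV4-34", "IGHV4-39", "IGHV5-51"),
        "J": ("IGHJ1", "IGHJ2", "IGHJ3", "IGHJ4", "IGHJ5", "IGHJ6"),
    },
    "IGK": {
        "V": ("IGKV1-5", "IGKV1-39", "IGKV2-28", "IGKV3-15", "IGKV3-20",
              "IGKV4-1"),
        "J": ("IGKJ1", "IGKJ2", "IGKJ3", "IGKJ4", "IGKJ5"),
    },
    "IGL": {
        "V": ("IGLV1-40", "IGLV1-44", "IGLV2-8", "IGLV2-14", "IGLV3-1",
              "IGLV3-21"),
        "J": ("IGLJ1", "IGLJ2", "IGLJ3", "IGLJ7"),
    },
}
_C_GENE = {"TRA": "TRAC", "TRB": "TRBC2", "IGH": "IGHM", "IGK": "IGKC",
           "IGL": "IGLC2"}

CELL_TYPE_ORDER = ("CD4_T", "CD8_T", "B", "NK", "MonoMac")


def default_length_law(receptor: str) -> dict[int, float]:
    """Discretized Gaussian CDR3 aa length law over 6..26.

    Mean 14 / sd 2 for TCR and mean 12 / sd 2 for BCR, so the modal lengths
    fall at 13–15 aa and 11–13 aa respectively, as observed in peripheral
    blood repertoires.
    """
    mean = 14.0 if receptor == "TCR" else 12.0
    lengths = np.arange(6, 27)
    w = np.exp(-0.5 * ((lengths - mean) / 2.0) ** 2)
    w /= w.sum()
    return dict(zip(lengths.tolist(), w.tolist()))


def default_vj_usage(receptor: str) -> dict[str, dict[str, dict[str, float]]]:
    """Geometric-decay base usage (ratio 0.8) over the built-in gene pools."""
    loci = TR_LOCI if receptor == "TCR" else IG_LOCI
    out: dict[str, dict[str, dict[str, float]]] = {}
    for locus in loci:
        out[locus] = {}
        for seg in ("V", "J"):
            genes = GENE_POOLS[locus][seg]
            w = 0.8 ** np.arange(len(genes))
            w /= w.sum()
            out[locus][seg] = dict(zip(genes, w.tolist()))
    return out


def default_composition() -> dict[str, dict[str, float]]:
    """Per-group PBMC cell-type mixes.

    CD4 T fractions are 55.15% (AD) and 49.16% (NC); the remaining mass is
    split so that CD8 T, NK and monocyte–macrophage fractions are lower in
    the disease group and B cells are equal.
    """
    return {
        "AD": {"CD4_T": 0.5515, "CD8_T": 0.22, "B": 0.12, "NK": 0.08,
               "MonoMac": 0.0285},
        "NC": {"CD4_T": 0.4916, "CD8_T": 0.25, "B": 0.12, "NK": 0.10,
               "MonoMac": 0.0384},
    }


@dataclass(frozen=True)
class NoiseConfig:
    """Contig-level corruption rates, each in [0, 1)."""

    nonproductive_frac: float = 0.05
    low_conf_frac: float = 0.05
    doublet_frac: float = 0.02


@dataclass(frozen=True)
class GroupSpec:
    n_samples: int
    cells_per_sample: int


def _default_groups() -> dict[str, GroupSpec]:
    return {"AD": GroupSpec(3, 2000), "NC": GroupSpec(2, 2000)}


@dataclass
class SyntheticConfig:
    """Full generator configuration; see module docstring for the model.

    ``expansion_mass`` and ``usage_tilt`` accept either one value for all
    groups or a ``{group: value}`` mapping (the two study arms differ in
    exactly these knobs).
    """

    receptor: str = "TCR"
    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    n_background_clones: int = 2000
    background_alpha: float = 5.0
    n_expanded_clones: int = 10
    expansion_mass: float | Mapping[str, float] = field(
        default_factory=lambda: {"AD": 0.15, "NC": 0.0})
    length_law: dict[int, float] | None = None
    vj_usage: dict[str, dict[str, dict[str, float]]] | None = None
    usage_tilt: float | Mapping[str, float] = 1.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    composition: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.receptor not in ("TCR", "BCR"):
            raise ConfigError(f"receptor must be TCR or BCR, got {self.receptor!r}")
        if not self.groups:
            raise ConfigError("at least one group is required")
        for g, spec in self.groups.items():
            if spec.n_samples < 1 or spec.cells_per_sample < 1:
                raise ConfigError(f"group {g!r}: empty group")
        for g in self.groups:
            phi = self.phi(g)
            if not (0.0 <= phi < 1.0):
                raise ConfigError(f"expansion_mass for {g!r} must be in [0, 1), got {phi}")
            if phi > 0 and self.n_expanded_clones < 1:
                raise ConfigError("n_expanded_clones must be >= 1 when expansion_mass > 0")
            if self.tau(g) < 1.0:
                raise ConfigError(f"usage_tilt for {g!r} must be >= 1")
        if self.background_alpha <= 0:
            raise ConfigError("background_alpha must be positive")
        for name, frac in (("nonproductive_frac", self.noise.nonproductive_frac),
                           ("low_conf_frac", self.noise.low_conf_frac),
                           ("doublet_frac", self.noise.doublet_frac)):
            if not (0.0 <= frac < 1.0):
                raise ConfigError(f"noise.{name} must be in [0, 1)")
        if self.length_law is None:
            self.length_law = default_length_law(self.receptor)
        _check_categorical("length_law", self.length_law)
        if self.vj_usage is None:
            self.vj_usage = default_vj_usage(self.receptor)
        for locus, segs in self.vj_usage.items():
            for seg, dist in segs.items():
                _check_categorical(f"vj_usage[{locus}][{seg}]", dist)
        if self.composition is None:
            self.composition = {g: default_composition().get(
                g, dict.fromkeys(CELL_TYPE_ORDER, 1 / 5)) for g in self.groups}
        for g in self.groups:
            _check_categorical(f"composition[{g}]", self.composition[g])

    def phi(self, group: str) -> float:
        if isinstance(self.expansion_mass, Mapping):
            return float(self.expansion_mass.get(group, 0.0))
        return float(self.expansion_mass)

    def tau(self, group: str) -> float:
        if isinstance(self.usage_tilt, Mapping):
            return float(self.usage_tilt.get(group, 1.0))
        return float(self.usage_tilt)

    def sample_ids(self) -> list[tuple[str, str]]:
        """[(sample_id, group)] in deterministic order."""
        return [(f"{g}{i + 1}", g)
                for g in self.groups for i in range(self.groups[g].n_samples)]

    def loci(self) -> tuple[str, str]:
        return ("TRA", "TRB") if self.receptor == "TCR" else ("IGH", "IGL")


def _check_categorical(name: str, dist: Mapping) -> None:
    p = np.array(list(dist.values()), dtype=float)
    if (p < 0).any():
        raise ConfigError(f"{name}: negative probability")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ConfigError(f"{name}: probabilities sum to {p.sum()!r}, not 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one :func:`simulate_repertoire` call."""

    config: SyntheticConfig
    #: clone_id, group, expanded, locus_1/cdr3_aa_1/cdr3_nt_1/v_1/j_1, locus_2/…
    clone_table: pd.DataFrame
    #: sample_id -> clone weight vector, aligned with the group's pool rows
    sample_weights: dict[str, np.ndarray]
    #: sample_id -> realized clone cell counts (same alignment)
    sample_clone_counts: dict[str, np.ndarray]
    #: one row per cell: sample_id, barcode, clone_id
    cell_assignments: pd.DataFrame
    expanded_clone_ids: set[str]
    #: group -> locus -> segment -> pd.Series of tilted usage probabilities
    group_usage: dict[str, dict[str, dict[str, pd.Series]]]
    #: barcodes carrying an injected same-locus doublet contig
    doublet_barcodes: set[str]
    #: barcodes with at least one contig passing all QC flags
    expected_kept_barcodes: set[str]
    #: barcodes with no corrupted contig and no doublet (clonotype-faithful)
    clean_singlet_barcodes: set[str]

    def clone_key(self, level: str = "nt") -> pd.Series:
        """Canonical clonotype key per clone (clone_id-indexed)."""
        col = f"cdr3_{'nt' if level == 'nt' else 'aa'}"
        t = self.clone_table
        pairs1 = t["locus_1"] + ":" + t[f"{col}_1"]
        pairs2 = t["locus_2"] + ":" + t[f"{col}_2"]
        key = np.where(pairs1 <= pairs2, pairs1 + ";" + pairs2,
                       pairs2 + ";" + pairs1)
        return pd.Series(key, index=t["clone_id"].to_numpy())


def _random_cdr3s(rng: np.random.Generator, lengths: np.ndarray
                  ) -> tuple[list[str], list[str]]:
    """I.i.d.-uniform aa sequences of the given lengths + codon-uniform nt."""
    total = int(lengths.sum())
    aa_idx = rng.integers(0, 20, size=total)
    codon_idx = np.floor(rng.random(total) * _AA_NCODON[aa_idx]).astype(int)
    aa_chars = np.frombuffer(AA_ALPHABET.encode(), dtype="S1")[aa_idx]
    codons = _CODON_LOOKUP[aa_idx, codon_idx]
    bounds = np.cumsum(lengths)[:-1]
    aa_seqs = [s.tobytes().decode() for s in np.split(aa_chars, bounds)]
    nt_seqs = ["".join(c) for c in np.split(codons, bounds)]
    return aa_seqs, nt_seqs


def _random_barcodes(rng: np.random.Generator, n: int) -> np.ndarray:
    """n distinct 16-mer droplet barcodes with the 10x '-1' suffix."""
    out: np.ndarray | None = None
    while out is None or len(np.unique(out)) < n:
        idx = rng.integers(0, 4, size=(n, 16))
        chars = np.frombuffer(b"ACGT", dtype="S1")[idx]
        out = np.array([c.tobytes().decode() + "-1" for c in chars])
    return out


def _tilted(base: Mapping[str, float], tau: float) -> pd.Series:
    p = pd.Series(base, dtype=float) ** (1.0 / tau)
    return p / p.sum()


def _build_clone_pool(rng: np.random.Generator, config: SyntheticConfig,
                      group: str, n_clones: int, used_keys: set[str],
                      start_id: int) -> pd.DataFrame:
    """Draw clone identities for one group; rejection keeps keys unique."""
    lengths_sup = np.array(list(config.length_law), dtype=int)
    lengths_p = np.array(list(config.length_law.values()), dtype=float)
    loci = config.loci()
    usage = {loc: {seg: _tilted(config.vj_usage[loc][seg], config.tau(group))
                   for seg in ("V", "J")} for loc in config.vj_usage}

    batches: list[pd.DataFrame] = []
    n_made = 0
    while n_made < n_clones:
        n_batch = n_clones - n_made
        if config.receptor == "TCR":
            locus2 = np.repeat("TRB", n_batch)
        else:
            locus2 = np.where(rng.random(n_batch) < 0.6, "IGK", "IGL")
        locus1 = np.repeat(loci[0], n_batch)
        cols: dict[str, np.ndarray] = {}
        for ci, locus_arr in ((1, locus1), (2, locus2)):
            L = rng.choice(lengths_sup, size=n_batch, p=lengths_p)
            aa, nt = _random_cdr3s(rng, L)
            v = np.empty(n_batch, dtype=object)
            j = np.empty(n_batch, dtype=object)
            for loc in np.unique(locus_arr):
                m = locus_arr == loc
                uv, uj = usage[loc]["V"], usage[loc]["J"]
                v[m] = rng.choice(uv.index.to_numpy(), size=int(m.sum()), p=uv.to_numpy())
                j[m] = rng.choice(uj.index.to_numpy(), size=int(m.sum()), p=uj.to_numpy())
            cols[f"locus_{ci}"] = locus_arr
            cols[f"cdr3_aa_{ci}"] = np.array(aa, dtype=object)
            cols[f"cdr3_nt_{ci}"] = np.array(nt, dtype=object)
            cols[f"v_{ci}"] = v
            cols[f"j_{ci}"] = j
        batch = pd.DataFrame(cols)
        p1 = batch["locus_1"] + ":" + batch["cdr3_nt_1"]
        p2 = batch["locus_2"] + ":" + batch["cdr3_nt_2"]
        key = (p1 + ";" + p2).where(p1 <= p2, p2 + ";" + p1)
        # collisions (within the batch or with earlier clones) are redrawn
        fresh = ~key.duplicated() & ~key.isin(used_keys)
        batch = batch[fresh]
        used_keys.update(key[fresh])
        batches.append(batch)
        n_made += int(fresh.sum())
    pool = pd.concat(batches, ignore_index=True)
    order = ["locus_1", "cdr3_aa_1", "cdr3_nt_1", "v_1", "j_1",
             "locus_2", "cdr3_aa_2", "cdr3_nt_2", "v_2", "j_2"]
    pool = pool[order]
    pool.insert(0, "group", group)
    pool.insert(0, "clone_id", [f"{group}_clone{start_id + i:05d}"
                                for i in range(n_clones)])
    n_bg = config.n_background_clones
    pool["expanded"] = np.arange(n_clones) >= n_bg
    return pool


def simulate_repertoire(config: SyntheticConfig
                        ) -> tuple[pd.DataFrame, list[SampleMeta], SyntheticTruth]:
    """Simulate contigs for every sample of the configured study design.

    Returns the contig table (canonical schema, all samples concatenated),
    the sample sheet, and the :class:`SyntheticTruth`.
    """
    rng = np.random.default_rng(config.seed)
    n_bg, n_exp = config.n_background_clones, config.n_expanded_clones
    n_pool = n_bg + n_exp

    used_keys: set[str] = set()
    pools = {g: _build_clone_pool(rng, config, g, n_pool, used_keys,
                                  start_id=0) for g in config.groups}
    clone_table = pd.concat(pools.values(), ignore_index=True)

    usage_truth = {
        g: {loc: {seg: _tilted(config.vj_usage[loc][seg], config.tau(g))
                  for seg in ("V", "J")} for loc in config.vj_usage}
        for g in config.groups}

    meta = [SampleMeta(sid, g, config.receptor) for sid, g in config.sample_ids()]
    frames: list[pd.DataFrame] = []
    sample_weights: dict[str, np.ndarray] = {}
    sample_counts: dict[str, np.ndarray] = {}
    assign_frames: list[pd.DataFrame] = []
    doublet_barcodes: set[str] = set()
    kept_barcodes: set[str] = set()
    clean_barcodes: set[str] = set()

    for sm in meta:
        g = sm.group
        pool = pools[g]
        n_cells = config.groups[g].cells_per_sample
        phi = config.phi(g)
        w = np.empty(n_pool)
        w[:n_bg] = (1.0 - phi) * rng.dirichlet(np.full(n_bg, config.background_alpha))
        w[n_bg:] = phi * rng.dirichlet(np.ones(n_exp)) if phi > 0 else 0.0
        counts = rng.multinomial(n_cells, w)
        clone_idx = np.repeat(np.arange(n_pool), counts)
        raw_bc = _random_barcodes(rng, n_cells)
        barcodes = np.array([f"{sm.sample_id}_{b}" for b in raw_bc])

        sample_weights[sm.sample_id] = w
        sample_counts[sm.sample_id] = counts
        assign_frames.append(pd.DataFrame({
            "sample_id": sm.sample_id, "barcode": barcodes,
            "clone_id": pool["clone_id"].to_numpy()[clone_idx]}))

        # two primary contigs per cell, stacked chain-1 block then chain-2
        parts = []
        for ci in (1, 2):
            parts.append(pd.DataFrame({
                "barcode": barcodes,
                "sample_id": sm.sample_id,
                "locus": pool[f"locus_{ci}"].to_numpy()[clone_idx],
                "v_gene": pool[f"v_{ci}"].to_numpy()[clone_idx],
                "d_gene": None,
                "j_gene": pool[f"j_{ci}"].to_numpy()[clone_idx],
                "cdr3_aa": pool[f"cdr3_aa_{ci}"].to_numpy()[clone_idx],
                "cdr3_nt": pool[f"cdr3_nt_{ci}"].to_numpy()[clone_idx],
                "raw_contig_id": np.char.add(raw_bc.astype(str),
                                             f"_contig_{ci}"),
            }))
        contigs = pd.concat(parts, ignore_index=True)
        contigs["c_gene"] = contigs["locus"].map(_C_GENE)
        n_contigs = len(contigs)
        contigs["umis"] = 1 + rng.poisson(2.0, n_contigs)
        contigs["reads"] = contigs["umis"] * (10 + rng.poisson(5.0, n_contigs))
        nonprod = rng.random(n_contigs) < config.noise.nonproductive_frac
        lowconf = rng.random(n_contigs) < config.noise.low_conf_frac
        contigs["productive"] = ~nonprod
        contigs["high_confidence"] = ~lowconf
        contigs["full_length"] = True
        contigs["is_cell"] = True

        corrupted = nonprod | lowconf
        ok_1, ok_2 = ~corrupted[:n_cells], ~corrupted[n_cells:]

        # same-locus doublets: a second, distinct chain-2 contig from a
        # different clone of the same pool
        is_doublet = rng.random(n_cells) < config.noise.doublet_frac
        d_idx = np.flatnonzero(is_doublet)
        if len(d_idx):
            partner = rng.integers(0, n_pool, size=len(d_idx))
            clash = partner == clone_idx[d_idx]
            while clash.any():
                partner[clash] = rng.integers(0, n_pool, size=int(clash.sum()))
                clash = partner == clone_idx[d_idx]
            extra = pd.DataFrame({
                "barcode": barcodes[d_idx],
                "sample_id": sm.sample_id,
                "locus": pool["locus_2"].to_numpy()[partner],
                "v_gene": pool["v_2"].to_numpy()[partner],
                "d_gene": None,
                "j_gene": pool["j_2"].to_numpy()[partner],
                "cdr3_aa": pool["cdr3_aa_2"].to_numpy()[partner],
                "cdr3_nt": pool["cdr3_nt_2"].to_numpy()[partner],
                "raw_contig_id": np.char.add(raw_bc[d_idx].astype(str),
                                             "_contig_3"),
            })
            extra["c_gene"] = extra["locus"].map(_C_GENE)
            extra["umis"] = 1 + rng.poisson(2.0, len(extra))
            extra["reads"] = extra["umis"] * (10 + rng.poisson(5.0, len(extra)))
            extra["productive"] = True
            extra["high_confidence"] = True
            extra["full_length"] = True
            extra["is_cell"] = True
            contigs = pd.concat([contigs, extra], ignore_index=True)
            doublet_barcodes.update(barcodes[d_idx])

        kept = ok_1 | ok_2 | is_doublet
        kept_barcodes.update(barcodes[kept])
        clean_barcodes.update(barcodes[ok_1 & ok_2 & ~is_doublet])
        frames.append(contigs)

    cols = ["barcode", "sample_id", "locus", "v_gene", "d_gene", "j_gene",
            "c_gene", "cdr3_aa", "cdr3_nt", "umis", "reads", "productive",
            "high_confidence", "full_length", "is_cell", "raw_contig_id"]
    all_contigs = pd.concat(frames, ignore_index=True)[cols]
    truth = SyntheticTruth(
        config=config,
        clone_table=clone_table,
        sample_weights=sample_weights,
        sample_clone_counts=sample_counts,
        cell_assignments=pd.concat(assign_frames, ignore_index=True),
        expanded_clone_ids=set(clone_table.loc[clone_table["expanded"],
                                               "clone_id"]),
        group_usage=usage_truth,
        doublet_barcodes=doublet_barcodes,
        expected_kept_barcodes=kept_barcodes,
        clean_singlet_barcodes=clean_barcodes,
    )
    return all_contigs, meta, truth


def simulate_cell_annotations(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate the per-cell annotation table (barcode, sample, cluster, type).

    Cell types are multinomial draws from each group's composition; the
    cluster label is a deterministic function of the cell type (one cluster
    per type), which is all the composition comparison consumes.
    """
    # separate stream: annotations are reproducible independently of contigs
    rng = np.random.default_rng([config.seed, 2654435769])
    cluster_of = {t: f"c{i + 1}" for i, t in enumerate(CELL_TYPE_ORDER)}
    frames = []
    for sid, g in config.sample_ids():
        comp = config.composition[g]
        types = list(comp)
        counts = rng.multinomial(config.groups[g].cells_per_sample,
                                 np.array([comp[t] for t in types]))
        cell_types = np.repeat(types, counts)
        rng.shuffle(cell_types)
        barcodes = _random_barcodes(rng, len(cell_types))
        frames.append(pd.DataFrame({
            "barcode": [f"{sid}_{b}" for b in barcodes],
            "sample_id": sid,
            "cluster": [cluster_of.get(t, "c0") for t in cell_types],
            "cell_type": cell_types,
        }))
    return pd.concat(frames, ignore_index=True)
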