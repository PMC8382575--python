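# clonoscope

Single-cell TCR/BCR repertoire comparison for two-group study designs,
with a fully seeded synthetic 10x-style V(D)J data generator.

Peripheral-blood immune repertoires shift measurably in disease: a handful
of clones expand, diversity drops, CDR3 length spectra and V/J segment
usage skew, and the cell-type mix of PBMCs changes. `clonoscope` implements
the standard comparison battery for such studies — here framed as an
Alzheimer's-disease (AD) vs normal-control (NC) design with 3 + 2 samples —
as a tested, reusable pipeline:

- **Clonotype assembly** from per-contig V(D)J annotation tables
  (10x `filtered_contig_annotations.csv` or AIRR Rearrangement TSV), with
  Cell-Ranger-style QC: flag filtering, cross-lineage doublet removal,
  best-contig-per-locus. A clonotype is the canonical sorted set of
  (locus, CDR3) pairs over a cell's kept contigs, nucleotide-level by
  default.
- **Expansion statistics**: top-N clonotype cell shares, log-decade
  frequency-interval histograms, within-group public clonotypes
  (Venn-style sharing counts).
- **Diversity**: per-sample Shannon entropy `H = −Σ pᵢ ln pᵢ` and inverse
  Simpson `D = 1/Σ pᵢ²` (the Hill number of order 2), compared across
  groups with Welch's t or exact/Monte-Carlo permutation.
- **Spectratyping and gene usage**: CDR3 amino-acid length distributions
  and V/J segment frequencies per sample and group, each category tested
  one-vs-rest on a 2×2 table — Pearson chi-square without continuity
  correction when all expected counts ≥ 5, otherwise two-sided Fisher
  exact.
- **Composition**: marker-panel labeling of clusters (CD4 T, CD8 T, B, NK,
  monocyte–macrophage; hemoglobin/platelet contamination excluded) and
  per-type proportion tests between groups.
- **Synthetic data**: per sample, clone weights are
  `(1−φ)·Dirichlet(α·1_S)` over a group-shared background pool
  concatenated with `φ·Dirichlet(1_E)` over E expanded clones; cells are
  multinomial draws, each clone carrying a fixed paired-chain identity
  with peaked CDR3 length laws and group-tiltable V/J usage. The single
  knob φ (expanded-clone mass) reproduces the oligoclonal-expansion /
  depressed-diversity signature; the generator returns the full ground
  truth for recovery tests.

## Worked example

```sh
clonoscope simulate --receptor TCR --cells 500 --seed 7 --out sim/
clonoscope run --config sim/config.yaml
clonoscope report sim/results
```

prints (output of this exact invocation):

```
[TCR]
  top-10 share AD: 12.9% (191 cells)
  top-100 share AD: 28.0% (416 cells)
  top-10 share NC: 3.2% (32 cells)
  top-100 share NC: 22.2% (220 cells)
  inv_simpson: AD=199.50, NC=425.06 (p=0.00394, welch_t)
  shannon: AD=5.80, NC=6.09 (p=0.0321, welch_t)
  public clonotypes AD: 143 (13.8%)
  public clonotypes NC: 72 (8.6%)
[composition]
  B: AD=12.80%, NC=14.20% (p=0.313)
  CD4_T: AD=56.40%, NC=46.10% (p=4.39e-07)
  ...
```

Read: the simulated AD arm carries an expanded-clone mass of 0.15, so its
top-10 clonotypes capture 12.9% of T cells against 3.2% in controls, and
its inverse-Simpson diversity (the effective number of dominant clones)
is roughly halved; the CD4 T-cell fraction is elevated by design
(55.15% vs 49.16% population values) and the one-vs-rest chi-square
detects it. All outputs are also written as TSV/JSON under
`sim/results/`.

The same analysis, step by step and with narrative output, lives in the
numbered drivers `analysis/01_simulate.py` … `analysis/05_composition.py`
(run them in order from the repository root; tables land in `results/`).

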