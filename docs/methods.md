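# Methods

## The comparison battery

The pipeline compares two groups of single-cell V(D)J repertoires (by
default a 3-sample disease arm, "AD", against a 2-sample control arm,
"NC") on five axes, mirroring the standard clinical-repertoire workflow:

1. **Top-N clonotype share.** Clonotypes are ranked by pooled cell count
   within a group (ties broken by canonical key, so results are
   machine-independent); the share is the fraction of the group's cells
   carried by the top N (default N ∈ {10, 100}). The denominator is
   *cells*, not clonotypes: a share of 18.8% paired with a cell count is
   only coherent under cell-share semantics. A clonotype-denominator
   variant is available through the frequency tables.
2. **Frequency-interval bins.** Clonotype frequencies are histogrammed
   into half-open intervals `(lo, hi]`; the default edges are the log
   decades 1e-4, 1e-3, 1e-2, 1e-1, 1. Bin counts always sum to clonotype
   richness.
3. **Public clonotypes.** A clonotype is public within a group if present
   in ≥ `min_samples` of its samples (default 2 — for a 2-sample group
   this is exactly the Venn intersection, and it is the weakest definition
   under which "no public clonotypes" is meaningful for a 3-sample group).
4. **Diversity.** Per sample, Shannon entropy `H = −Σ pᵢ ln pᵢ` and
   inverse Simpson `D = 1/Σ pᵢ²`. Natural log is the default: the Hill
   ordering `D ≤ exp(H)` then holds by construction, which is how the two
   indices remain mutually consistent at repertoire richness scales (under
   log₂ the printed pairs typical of such studies would violate it).
   Groups are compared on the per-sample values, not on pooled
   repertoires; the default test is Welch's t (with n = 3 vs 2, an exact
   permutation test cannot go below p = 0.1, so permutation is offered as
   an option rather than the default).
5. **Spectratype / V-J usage / composition.** Per length, gene, or cell
   type: a one-vs-rest 2×2 table (this category vs all others, group vs
   group) tested with Pearson's chi-square without continuity correction
   (`Σ(O−E)²/E`, df = 1), switching to the two-sided Fisher exact test
   (sum of hypergeometric point probabilities ≤ the observed table's)
   whenever any expected count falls below 5 — the standard SPSS-style
   switch rule. Yates correction and Benjamini–Hochberg adjustment are
   flags, both off by default since per-category comparisons are
   conventionally reported unadjusted in this setting.

## QC and clonotype identity

Contigs are kept iff `is_cell ∧ high_confidence ∧ full_length ∧
productive` with a non-null CDR3 nucleotide sequence. Barcodes carrying
both TR and IG productive chains are removed entirely (cross-lineage
doublets); within a (barcode, locus) only the contig with the most UMIs
survives (ties: more reads, then lexicographically smallest contig id).
The clonotype key is the sorted set of (locus, CDR3-nt) pairs of a
barcode's kept contigs; an amino-acid-level key is a flag (public-clone
sharing is sometimes defined on aa). Barcodes are sample-prefixed at read
time, so pooling samples within a group can never collide cells.

## The generator

`simulate_repertoire` emulates a 10x 5' V(D)J experiment at the level the
statistics consume:

- **Clone pool.** Each group owns a pool of `S_bg` background clones plus
  `E` expanded clones. Each clone has a fixed paired-chain identity:
  TRA+TRB for TCR, IGH plus one light chain (IGK with probability 0.6)
  for BCR. CDR3 amino acids are i.i.d. uniform over the 20 residues at a
  length drawn per clone from the length law; nucleotides are
  codon-uniform back-translations. Key collisions between independently
  drawn clones are rejected and redrawn, so the clone partition is
  unambiguous ground truth.
- **Clone sizes.** Per sample, weights are
  `(1−φ)·Dirichlet(α·1_{S_bg}) ⊕ φ·Dirichlet(1_E)` and cell counts are
  multinomial. φ (`expansion_mass`, per group) is the interpretable
  expansion knob; φ_AD = 0.15, φ_NC = 0 by default.
- **Usage tilt.** Group usage is `base^(1/τ)` renormalized; τ = 1 means no
  skew. Defaults use a geometric-decay base (ratio 0.8) over built-in
  human segment name pools.
- **Noise.** Independent per-contig corruption (non-productive 5%,
  low-confidence 5%) and same-locus doublet barcodes (2%) that receive a
  second, distinct TRB/IGH contig. UMIs are `1 + Poisson(2)`; reads are
  `umis × (10 + Poisson(5))`.
- **Annotations.** Cell types are multinomial per group; the default mixes
  put CD4 T at 55.15% (AD) vs 49.16% (NC) with CD8/NK/mono-mac lower in
  the disease arm and B equal.

All randomness flows from one seeded `numpy.random.Generator`; a fixed
seed gives byte-identical output and the cell-annotation stream is
decoupled from the contig stream.

### Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| groups | AD: 3 × 2000 cells, NC: 2 × 2000 | the 3-vs-2 design; 2000 cells/sample keeps desk-scale runs in seconds while leaving hundreds of clones per sample |
| `S_bg` | 2000 | richness comparable to cells/sample, giving control-arm inverse-Simpson in the hundreds, as in healthy blood |
| `background_alpha` | 5.0 | polyclonal background: even enough that an unexpanded repertoire's top-10 cell share stays well under 15%, while still heavy-tailed through multinomial sampling |
| `E`, φ | 10, {AD 0.15, NC 0} | ten expanded clones match the top-10 readout; 0.15 reproduces a several-fold diversity drop without degenerate repertoires |
| length law | discretized Gaussian, mean 14 (TCR) / 12 (BCR), sd 2 over 6–26 aa | modal lengths 13–15 aa (TCR) and 11–13 aa (BCR), the peaks observed in peripheral blood |
| noise | 0.05 / 0.05 / 0.02 | typical fractions of non-productive, low-confidence and multi-chain artifacts in filtered 10x output |

## What the generator does and does not emulate

It reproduces the statistical structure the comparisons rest on:
heavy-tailed clone sizes with a controllable expansion mass, peaked length
spectra, tiltable segment usage, paired chains, contig-level noise. It
does **not** model V(D)J recombination biology — no D segments, germline
reference sequences, somatic hypermutation, or biased junctional
chemistry — and within-group clone sharing is far higher than between real
individuals, because a group's samples draw from one shared pool rather
than from private recombination repertoires. Passing recovery tests
therefore demonstrates correctness of the pipeline's bookkeeping and the
direction/size of expansion effects, not realistic public-clonotype rates
or germline-level usage estimates.

A related caveat applies to the per-gene and per-length tests themselves:
cells of one clone share their V/J genes and CDR3 lengths, so under strong
clonal expansion the 2×2 counts are cluster-correlated and the tests are
anti-conservative — visibly so in the default simulation, where the
expanded clones alone skew the usage tables. This is intrinsic to testing
cell-level counts (the convention this battery follows), not an
implementation artifact; the type-I calibration guarantee is therefore
verified in the singleton-clone regime (background pool ≫ cells), where
observations are independent and the nominal level is the right
reference. The clonotype counting unit (`unit="clonotype"`) softens but
does not remove the correlation, since clones shared across a group's
samples are still counted repeatedly.

## Numerical choices

- Frequencies are exact ratios of integer counts; scope sums are asserted
  to 1 within 1e-12.
- Permutation p-values use `≥ observed − 1e-12` to make ties count as
  extreme; Monte-Carlo p-values are add-one corrected
  (`(hits+1)/(n+1)`), exhaustive ones are exact fractions.
- Marker scoring z-scores each gene across clusters with population sd;
  zero-variance genes contribute 0. `min_margin = 0.1` (in mean-z units)
  forces "unassigned" on clusters whose best and runner-up panels are
  indistinguishable — CD4 vs CD8 T share three of their markers, so the
  disambiguating genes must carry at least that much signal.
- Degenerate 2×2 tables (a zero margin) raise rather than return p = 1;
  callers that sweep categories record such rows as untested.
- Result floats are serialized at 6 significant digits; re-running a
  pipeline with the same config and seed is byte-identical.

## Problem sizes in tests

The statistical test suite uses 3 × 5000-cell samples over 50 seeds for
the expansion sweep, 100 seeds for the power and calibration checks, and
10,000 cells per group for the composition comparison; the exhaustive
Fisher cross-check enumerates every 2×2 table with total ≤ 50 (311,150
tables). These sizes were chosen so each guarantee is measured with a
binomial standard error small against its margin while the whole suite
stays desk-scale.

## Interface design

The command line deliberately exposes only three verbs — `simulate`, `run`
(the whole battery from one YAML config) and `report` — because every
intermediate stage is a single library call and the numbered drivers under
`analysis/` already provide stage-by-stage entry points with narrative
output; nine thin subcommands would duplicate that orchestration without
adding capability. The CLI performs no computation of its own: every
number in `summary.json` is reproducible by calling the corresponding
module function directly, which the test suite asserts.

## Known limitations

- No rarefaction or richness extrapolation (Chao-type estimators) and no
  repertoire-overlap indices beyond sharing counts; diversity comparisons
  are on plug-in indices, which are downward-biased at low cell counts —
  comparable across arms of equal depth, but not absolute.
- The frequency-interval edges of published analyses are rarely stated;
  the log-decade default is a documented convention, configurable per run.
- Cluster labeling consumes a cluster × gene mean-expression matrix;
  upstream normalization and clustering are out of scope.
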