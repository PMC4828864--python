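# Methods

## Fixed human-lineage substitution scan

A position counts as a fixed human-lineage substitution when (i) all human
haplotypes in the panel carry the same residue (`is_fixed_in_humans`), (ii)
the three outgroup sequences yield a consensus (`outgroup_consensus`), and
(iii) the two residues differ. The default consensus mode is **unanimous**
(all three outgroups agree); a **majority** mode (any residue ≥ 2 of 3) is
provided because reference-genome panels sometimes disagree at single sites.
Columns containing a gap (`-`) or unknown residue (`X`) in *any* sequence
are skipped without error: they correspond to positions that cannot be
aligned across all four genomes and therefore carry no evidence either way.
Positions are reported 1-based on the ungapped first human haplotype, the
numbering used for the PCDHB11 reference set. Substitutions are counted per
amino-acid position: if multiple base changes hit one codon they appear as
one substitution, since the scan operates at protein level (CDS input is
translated first with the standard code; stops become `*`, unresolvable
`N`-codons become `X`).

## GO surface filter

Filtering is on literal GO term *names*, not the ontology graph: membrane
condition = exact match of "integral component of plasma membrane" or
"anchored component of external side of plasma membrane"; neural condition =
some term starts with `nervous`/`neuron`/`dendr`/`axon`/`synap` and does
not contain `enteric`/`autonomous`/`synaptonem`/`axonem`/`dendritic cell`.
Exclusion substrings always override inclusion prefixes, but only within
the same term — an excluded term elsewhere in the set does not disqualify a
protein that also has a qualifying term. Matching is case-sensitive by
default (annotation names are lowercase); `ignore_case=True` lowercases
first. Because surface annotation is incomplete, families — proteins whose
UniProt-style accessions share the first three characters — are included
whole when any member passes; the expansion is idempotent and monotone. A
graph-traversal (ancestor propagation) mode would be a natural extension
and is deliberately not implemented.

## Exchange-rareness weights

Off-diagonal substitution-matrix entries are mapped decreasingly onto
integer weights in [3, 15]. Two routes exist:

* **Frozen BLOSUM100 calibration.** The published PCDHB11 pair weights
  determine the map exactly: a brute-force fit of rounded affine maps over
  the twelve (score, weight) pairs gives `w = 5 − s` with no residual, so
  slope −1 / intercept 5 is frozen (`FROZEN_BLOSUM100_CALIBRATION`). The
  bundled BLOSUM100 (loaded from biotite's matrix database) has
  off-diagonal range [−10, 4] rather than the [−10, 2] the endpoints imply,
  so the result is clipped into [3, 15]; clipping affects only the four
  commonest exchanges (F/Y, I/V, K/R, L/M → 3) and leaves D/W (−10) as the
  unique weight-15 exchange, consistent with "commonest exchanges weigh 3,
  the rarest 15". An explicit lookup-override layer
  (`WeightTable.with_overrides`) exists for the case where a matrix variant
  fails to reproduce the published weights; with the bundled matrix it is
  **not engaged**, and overridden pairs are always flagged on the table.
* **Generic endpoint map** for any other matrix: max off-diagonal score → 3,
  min → 15, affine in between, rounded half-away-from-zero. Rate or
  exchangeability matrices (e.g. the JTT data, biopython's `JONES`), whose
  scale is not log-odds, are rank-transformed first (highest rate → 3).

Per-protein scores add the weights of all substitutions; ratios divide by
protein length. Ranking sorts descending by the chosen key with ties broken
by (substitution count desc, protein id asc). Ranking the published
23-protein table by exact recomputed ratios reproduces its printed order;
the printed 3-decimal ratios themselves contain ties that the exact values
resolve. Matrix robustness is measured as the Spearman correlation between
rankings (`compare_rankings`).

## Intra-human variability

Variability of a gene = number of missense + nonsense + stop-lost +
frameshift records in a dbSNP-like extract. The default counts *records*
(a plain sum of mutation entries); `distinct_positions=True` counts
positions instead, collapsing multi-allelic sites — provided because
"variable positions" and "sum of mutations" differ exactly when
multi-allelic records occur. Cluster summaries report min/max/median (even
cluster sizes: mean of the middle two) and whether a focal gene exceeds the
median.

## Aggregation-assay quantification

* **Triangle threshold.** On a 256-bin histogram, a line joins the peak to
  the far end of the nonzero range on the longer-tail side (tie → brighter
  side); the threshold is the bin of maximal perpendicular distance to that
  line (tie → bin nearest the peak), offset one bin toward the tail. This
  convention is frozen and oracle-tested (exhaustive distance search); it is
  documented as *a* triangle variant, not claimed bit-identical to any
  particular plugin (pre-smoothing and background flags vary between
  implementations). Non-8-bit images are binned into 256 equal-width bins
  over their observed range.
* **Clusters.** Connected components of the binary mask, 8-connected by
  default (configurable to 4), with areas below 100 px discarded.
* **Spherical model.** A cluster of N cells projects
  `round(A₁ · N^(2/3))` px for single-cell area A₁; with A₁ = 150 px the
  10- and 30-cell cutoffs are 696 and 1448 px. Classes: small < 696 ≤
  medium ≤ 1448 < large, i.e. the medium ("10–30 cells") class is closed on
  both ends. A₁ is estimated from control images as the center of the most
  populated 10-px area-histogram bin (ties → smaller bin).
* **Adhesive strength** = fraction of ≥10-cell clusters, divided by the
  same-day reference condition's fraction (error if the reference has
  none).
* **Mixing.** Channel masks are combined by logical OR (equivalent to
  adding binary masks); the 100-px floor applies to the *union* components;
  a cluster is mixed when it overlaps ≥1 pixel of each channel mask. With
  noisy rendered images, single above-threshold noise pixels of the other
  channel inside a cluster inflate the mixed fraction (an analogue of
  bleed-through in real micrographs); the readout is therefore interpreted
  relative to control pairs, which carry the same background — the two-way
  design below — and the unbiasedness of the statistic itself is verified
  on noise-free ground-truth masks.
* **Statistics.** One-way ANOVA + Tukey HSD over per-day normalized
  strengths; for mixing, a two-way ANOVA (population identities and
  interaction, `statsmodels` OLS / type-II) plus per-subpanel linear-model
  contrasts against control with Bonferroni correction. Both require ≥2
  conditions with ≥2 replicates.

## Synthetic data: what it emulates, what it does not

* **Panels** plant fixed substitutions on a random background: all human
  haplotypes carry the derived residue, outgroups the ancestral one;
  elsewhere human and outgroup consensus agree, with iid per-site,
  per-haplotype polymorphism (default rate 0; noise never touches planted
  sites, so fixation is testable at any rate; a `break_fixation` flag flips
  one haplotype for negative tests). Not emulated: linkage, indels,
  alignment error, codon structure (CDS mode would back-translate with
  fixed codons), realistic site-frequency spectra. A green scan test
  therefore establishes correctness of the column logic, not robustness to
  alignment artifacts.
* **Variant tables** reproduce requested per-gene class totals exactly with
  shuffled rows and distinct positions — no allele frequencies or real
  dbSNP density.
* **Images** place non-overlapping disks whose pixel areas follow the
  spherical law *exactly*: each cluster takes the `area` pixels nearest its
  center (exact-area rasterization, chosen over midpoint-circle fill
  because it makes ground truth exact rather than ±1 px). Cells per
  cluster default to a zero-truncated geometric (long-tailed small-cluster
  regime); three presets (`ADHESION_PRESETS`, geometric p = 0.8/0.35/0.15)
  emulate the no-protocadherin / weak / strong adhesion regimes with
  expected ≥10-cell fractions ≈ 0 / 2% / 23%. Mixed clusters are split
  half-and-half between channels. Rendering adds iid Gaussian noise
  (default sd 8 on a 20/220 background/foreground, 8-bit) — no PSF, uneven
  illumination, overlapping clusters or out-of-focus cells; a green
  pipeline test establishes the measurement chain, not segmentation
  robustness on real micrographs.
* Determinism: one `numpy` generator seeded per call; identical spec + seed
  is bit-identical.

## Numerical choices

Rounding is half-away-from-zero throughout (cutoffs: 696.22 → 696, 1448.25
→ 1448; weights likewise). Weight-table lookups on pairs absent from the
table raise rather than default. Degenerate inputs raise named errors:
constant-off-diagonal matrices, empty area lists, all-zero histograms,
zero-strength references, mismatched gene sets, unplaceable cluster
layouts. The genome-scale published counts (329 surface proteins, 136 with
substitutions, variability 92–167 with median 139) depend on external
database versions and are validated only as property-based recounts on
synthetic universes, never asserted against those literals.
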