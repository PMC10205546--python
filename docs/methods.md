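# Methods

This note documents the models, rules and numerical choices implemented in
`hnsomics`, and what the synthetic-study generator does and does not
emulate.

## Study design and data model

The design is two tissues — SON (cell bodies/dendrites) and NIL (axonal
terminals) — each with 6 control and 6 water-deprived (WD) replicates, the
standard power point for detecting ≥ 2-fold protein changes in this kind
of TMT experiment. Sample metadata travels in an explicit design table
(sample_id, tissue, condition, replicate) rather than in column-name
conventions. Abundance matrices carry a `scale` tag (`raw`, `log2`,
`log2_adjusted`); missing values are explicit (`NaN`, empty TSV cell) on
every scale, never zero — a zero reporter intensity and an unobserved
value are different things, and no imputation is performed anywhere.
Features lacking two values per condition are excluded from that test and
counted in a skipped-features report. All protein coordinates are 1-based
residue numbers.

## Normalization

Per-sample factors equalize total raw abundance:
factor_s = mean(column totals) / total_s. The target constant (mean of
totals) is a free choice — any positive target produces identical fold
changes and p-values, shifting only the absolute log2 values; this
scale-equivariance is asserted by a test. The **total-protein** factors are
re-applied to the phosphopeptide table: total phospho signal is expected to
move with the stimulus, so it is a poor loading metric. After scaling,
zeros become missing and values are log2-transformed.

One intrinsic caveat, worth stating because the generator plants known
effects: normalizing to total signal confounds a (small) global
differential content with loading. With 5% differential features at
|log2FC| = 1 the induced common shift is ≈ 0.02 log2 units, identical for
every feature in a sample. Adjusted phosphopeptide fold changes are immune
(the correction subtracts the same per-sample constants), and the planted
proteome effects are recovered to well within classification tolerance;
recovery of proteome log2FC is therefore exact only up to this
compositional offset.

## Master proteins and phosphosite grouping

"Annotation quality" for master-protein selection is operationalized as
the count of populated annotation fields, with ties broken to the
lexicographically smallest accession — a deterministic, documented proxy.
Phosphosite localization uses a strict > 70% confidence rule; passing PSMs
group by (sequence, exact site list), failing PSMs by (sequence, phosphate
count), flagged unlocalized but still quantified. Mixed per-site
confidences on multi-site peptides are treated per-peptide, not per-site.
Group abundance is the **sum** of member PSM abundances (reporter-ion
signal is additive), which makes grouping conserve per-sample total signal
exactly — a tested invariant.

## Differential statistics

Welch's unequal-variance t test, two-sided (volcano plots are two-sided by
construction; sidedness is otherwise a free choice). Degenerate inputs are
resolved explicitly: two zero-variance groups with equal means give
(t = 0, df = n1+n2−2, p = 1); with unequal means, p = 0 with a `degenerate`
flag. The headline classification is uncorrected p < 0.05 (strict), up or
down by the sign of log2FC; a Benjamini–Hochberg column is emitted
alongside for transparency but never used for classification — the
uncorrected rule is the workflow's deliberate, documented choice for
heterogeneous brain tissue. PCA is computed per tissue on all features
with complete data, feature-centered, via SVD, with a deterministic sign
convention (largest-magnitude loading positive per component).

## Cumulative phosphorylation state (ΔPs)

Per gene, pooling isoform accessions: ΔPs = Σ log2FC over phosphopeptide
groups with p < 0.05, computed on **adjusted** (protein-corrected)
abundances — the adjusted table is the stated analysis object of the
workflow; an unadjusted variant is a switch away in the API. Genes with no
significant peptide are omitted rather than scored 0, so neutral ≠
untested. The cutoff is 2 × the mean per-peptide sample SD (n−1
denominator) of adjusted log2 abundances, pooled across both conditions;
classification is strict (|ΔPs| exactly at the cutoff is neutral). The
cutoff is computed at full precision; the familiar ±0.34 / ±0.40 values
arise from rounded mean SDs of 0.17 / 0.2 and are reproduced as worked
examples. Note that (0.15 + 0.19)/2 is not exactly 0.34 in binary floating
point; the `cutoff = 2 × mean SD` identity is exact, the decimal rendering
is compared at 1e-12.

Site mapping places a localized group's sites at
match_start + peptide_offset − 1 on the parent sequence, reporting every
match position with an ambiguity flag when the peptide recurs; residue
mismatches are hard errors.

## MCN reference list and integration

Single-cell counts are normalized per cell to a constant total (10,000)
then log1p — the conventional recipe where the upstream pipeline's exact
settings are unknowable. A cluster is MCN when its mean normalized
expression of (Avp OR Oxt) and of Caprin2 both exceed the threshold
(default 1.0); selection operates on provided cluster labels, with a
seeded k-means fallback for unlabeled matrices — graph-based clustering is
out of scope. The MCN gene list keeps genes with mean normalized count
strictly > 0.5 over the MCN cells; the cutoff, not any "top X%"
description, is the rule, and the fraction it retains depends on the gene
universe size. Transcriptome merging keeps genes with counts strictly > 10
in either strain. The Venn decision table is a pure function of three
booleans and partitions the universe (tested property). Spearman
correlations use average ranks; the two-sided p comes from full
permutation enumeration for n ≤ 9 and the t-approximation otherwise.
Over-representation uses the hypergeometric upper tail against an explicit
background with BH adjustment across tested terms — deliberately plainer
and more reproducible than tool-specific corrections (e.g. g:SCS); terms
outside [3, 2000] genes after background intersection are skipped and
reported. Functional classification joins a user-supplied two-column
table (live pharmacology/TF databases are not fetched); unmapped genes
are "unclassified".

## Synthetic-study generator

Defaults are the study conditions and are not tuned per run:
6 vs 6 samples; 1500 proteins per tissue (a desk-scale stand-in for the
~7,500–8,200 of a full experiment); 5% differential proteins at
|log2FC| = 1.0 (half up, half down); ~2 phosphopeptides per protein with
8% carrying occupancy effects of |log2FC| = 0.8; residual SD 0.2 on the
log2 scale (matching the 0.17–0.2 mean adjusted-peptide SDs such data
shows); per-sample loading factors s^U(−1,1) with s = 1.5, shared between
the proteome and phospho tables of a tissue; 20% of PSMs below the 70%
localization threshold; 92% of the universe detected per tissue; 2% of
genes carrying a second isoform accession.

Differential counts are fixed by the rounding rule ⌊frac × n⌋, never
sampled, so tests can assert them. Peptide abundances ride on the parent
protein's *realized* per-sample log2 values, so protein-level adjustment
recovers planted occupancy exactly in the noise-free limit (a tested
identity). Cross-compartment coupling is planted gene-wise on the NIL
phospho-differential genes: 30% get a same-sign SON proteome effect
(transport-then-phosphorylate; drives the positive SON-proteome vs NIL-ΔPs
correlation) and a disjoint 30% get an opposite-sign NIL proteome effect
(phosphorylate-then-secrete; drives the negative NIL-ΔPs vs NIL-proteome
correlation). The single-cell module plants ⌊frac × n⌋ MCN cells with
markers at a fixed low baseline elsewhere and a 50× MCN multiplier, plus
an MCN expression program covering most differential genes; transcriptomes
are log-normal around a stated median with a controllable expressed-set
overlap.

**Not emulated:** spectra, missed cleavages, TMT reporter interference,
isotopic impurity, peptide-level missingness structure, batch effects,
compositional biology of real tissue, or real marker co-expression
topology. Passing tests demonstrate that the *procedures* are correct and
well-calibrated under the stated generative model, not that the biological
conclusions of any particular real dataset would replicate.

## Problem sizes and replication counts

Monte-Carlo checks use sizes chosen once for precision at desk scale:
type-I calibration on 2000 null features (tolerance 3 binomial SEs);
proteome recovery on 1000 proteins; ΔPs direction recovery pooled over 20
replicate studies of 300 proteins; correlation-sign recovery over 100
replicate studies of 600 proteins (the sign criterion needs ~100+ genes in
the correlation join for stable significance, which 600 proteins provide);
the planted-marker contrast checked across 25 seeds. The acceptance script
reports each value with the problem size it used.

## Known limitations

* The proteome noise-free recovery is exact only up to the compositional
  normalization offset described above.
* Exact Spearman permutation p is enumerated only to n = 9 (9! pairings);
  beyond that the t-approximation is standard but approximate.
* The ΔPs cutoff inherits any occupancy-effect variance into the pooled
  SD, so planted effects slightly widen the band relative to a pure-noise
  SD — intrinsic to pooling both conditions.
* Unlocalized groups keyed by (sequence, count) can merge genuinely
  different site stoichiometries; this mirrors the per-peptide reading of
  the localization rule.
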