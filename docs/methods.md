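# Methods

This note documents the models and conventions the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a user should know about
before trusting a result.

## Quantification model

**RPKM.** Both assays are normalized as reads per kilobase of *coding
sequence* per million mapped reads. The CDS denominator is used for the
RNA assay as well, so that the ratio of the two densities is taken over
the same length term. The per-sample "mapped total" is the column sum over
the analysed genes; RPKM is therefore invariant to rescaling any one
library, and — importantly — carries no absolute scale.

**Detection filter.** A gene is analysed when its raw read total is at
least `min_reads` (default 10) in *both* assays, pooling replicates within
each condition, in every condition of the comparison set. The pipeline
applies the filter per contrast: a gene undetectable only in an unrelated
tissue library still enters an adipogenesis contrast. The boundary is
inclusive and the filter is monotone in `min_reads`.

**Translational efficiency.** `Eff = (RPKM_RPF + c) / (RPKM_RNA + c)` per
matched (condition, replicate) pair, default pseudocount c = 0. Zero RNA
signal yields NaN (undefined), never infinity. Because each library is
depth-normalized, Eff is identifiable only *up to a per-sample constant*:
a hypothetical efficiency shared by every gene would scale the RPF library
total and cancel. All downstream uses respect this — they compare Eff (or
its fold change) between genes, gene sets, or conditions, never its
absolute level.

## Fold changes and the decomposition identity

Per assay, `log2 FC = log2((mean_b + c) / (mean_a + c))` over
replicate-averaged RPKM with pseudocount c = 0.5. The efficiency component
is *computed as* `log2 FC_RPF − log2 FC_RNA`, which makes the additive
decomposition identity exact to machine precision by construction rather
than a property to be verified numerically.

**Median centering (default).** Depth normalization is compositional:
when strongly regulated genes move a substantial share of library mass
between conditions, every gene's raw ratio shifts by the same constant
(about −0.5 log2 under the generator's default 20%-regulated, ~8–10×
scenario). The default `center="median"` subtracts the per-assay median
log2 fold change across genes, removing that shared offset under the
standard assumption that most genes are unregulated — the same rationale
as median-of-ratios library-size estimation. `center="none"` gives the
raw ratios for designs where the assumption fails.

## Driver classification

Genes with `|log2 FC_RPF| ≥ log2(T)` (T = 4 for differentiation
contrasts, 2 for the tissue contrast) are partitioned by the relative
magnitude of the RNA component a and the efficiency component b against a
component threshold `c = log2(T)/2`:

- translation-driven: `|a| < c`
- RNA-driven: `|b| < c`
- synergistic: both ≥ c with the same sign
- both ≥ c with opposite signs: the larger-magnitude component wins
  (an exact tie would imply a zero RPF change and cannot pass the gate)

Groups 1–3 are up (by the sign of the RPF change), 4–6 down; the partition
is exhaustive and mutually exclusive for every gene passing the gate. The
choice `c = log2(T)/2` makes the three categories cover the plane for both
T values; it is configurable.

**Contribution estimate.** The global share of the translational
component is estimated by the ratio of correlations: `r_eff =
corr(ΔEff, ΔRPF)` and `r_rna = corr(ΔRNA, ΔRPF)` on replicate-averaged
fold changes, each divided by the replicate-to-replicate RPF fold-change
correlation `r_rep` (the reproducibility ceiling), then normalized to
percentages. Percentages are withheld when `r_rep ≤ 0` or either ratio is
non-positive (pure noise in one component makes its share undefined).
The estimate is reported as an *ordering* statistic across scenarios —
with shared measurement error in ΔEff and ΔRPF it is not an unbiased
variance decomposition.

## Metagene analysis

The P-site of a footprint is placed a fixed 14 nt beyond its 5′ end for
all read lengths; reads shifted past the transcript end are dropped and
counted. Coordinates are 0-based, half-open, transcript-relative.

Each gene's windowed P-site vector is divided by that gene's mean CDS
density before averaging (a uniformly covered CDS contributes exactly 1.0
at every in-CDS offset), making the profile invariant to per-gene scaling.
Default windows are −50..+100 nt around the first nucleotide of the start
codon and −100..+50 around the first nucleotide of the stop codon; genes
too short for part of the window simply contribute to fewer offsets.

The periodicity score is `max(f0, f1, f2) − 1/3` over the codon-frame
fractions of in-CDS P-sites, with a chi-square test against uniformity;
0 for RNA-like coverage, 2/3 for perfectly framed footprints.

## Cumulative-distribution machinery

The two-sample KS statistic D is evaluated over the pooled support. Three
p-value modes: asymptotic (Kolmogorov distribution at effective
n = n_x·n_y/(n_x+n_y)); exact enumeration of all C(n_x+n_y, n_x) label
assignments for pooled sizes ≤ 12 (equal to the distribution-free exact
null distribution when there are no ties); and seeded permutation with the
observed assignment included, so p ≥ 1/(n_permutations + 1).

Set-shift tests compare a gene set against its complement by default
(independent samples); the `all_genes` background reproduces
cumulative-fraction plots drawn against the full population. Ranked
enrichment uses the classic unweighted KS running sum with gene-label
permutations; NES is ES divided by the mean permuted |ES|. Category
enrichment is an upper-tail hypergeometric test; Benjamini–Hochberg FDR
is reported alongside raw p-values when many sets are tested.

## microRNA repression analysis

Member microRNAs sharing a seed are collapsed to one family (targets:
union; per-gene site count: maximum over members). Within a tissue, a
family's detected targets are compared to all other analysed genes on
log2(x+1)-transformed values by KS; the effect size is the ratio of
linear-scale means. A family counts as repressing when the ratio is < 1
and p < 0.05. Families with fewer than 10 detected targets are skipped.
Cross-tissue comparisons apply the same test to log2 fold changes, with
the ratio of mean linear fold changes as the effect size.

The stronger-repression fraction compares each family's target/non-target
ratio between tissues, restricted to families significantly repressed in
at least one tissue (ties excluded and reported). The site-density
analysis ranks genes by fold change, splits them into 20 equal-size rank
bins (ties broken by gene id), and fits the per-bin mean total conserved
site count on the bin index by ordinary least squares.

## Synthetic-data generator

The generator emulates the paired six-condition design (brown/white
lineages at D0/D5 plus BAT/WAT depots, duplicates, RPF + RNA per sample).

**Counts.** RNA counts are negative binomial with mean
`baseline_RPKM × 2^condition_effect × (CDS kb) × (library_size / 10^6)`;
RPF means are further multiplied by the gene's baseline efficiency and
the condition's Eff effect. Dispersion 0 selects the Poisson limit.
Defaults: dispersion 0.05, library size 2×10⁷ reads (deep modern
libraries, comfortably above the ten-million-read scale of the design the
package targets), baseline RPKM log-normal with median 20 and ln-sd 1,
baseline Eff log-normal with median 1 and ln-sd 0.4, duplicates.

**Regulation classes.** Per contrast, fixed fractions of genes (default
2% + 4% + 4% up and the same down — 20% regulated, 1000 of 5000 genes)
are allocated to the six classes by exact count via a seeded permutation,
so group sizes are deterministic. Driving components draw |log2| from
(2.6, 3.4), synergistic components from (1.8, 2.4) (same sign), minor
components from (0, 0.25) with the sign of the regulated direction. These
ranges put the planted classes clearly on their own side of the component
threshold (1.0) relative to the fold-change noise floor at duplicates and
dispersion 0.05 (per-gene log2 FC sd ≈ 0.33, Eff component ≈ 0.47), which
is what makes ~90%+ class recovery a property of the *method* rather than
of luck. The additive identity holds exactly in the truth by construction.

**microRNA families.** 219 seed families (the count of conserved families
the targeting databases provide for mouse), default 50 conserved targets
each, at least one site per target with Poisson extras (mean site count
1.5). Per-family repression strengths are uniform on (0.2, 0.5) log2 with
a +0.3 bonus in the stronger tissue; 75% of families repress more
strongly in BAT. Repression acts multiplicatively on the RNA mean, the
Eff mean, or both, only in the tissue conditions. Strengths stack across
families targeting the same gene, so defaults are deliberately modest:
with ~2.2 families per gene the mean stacked repression is ~1.3 log2,
keeping tissue libraries within a realistic range of the others. (Earlier,
stronger per-family defaults stacked to a ~10× global knockdown — a
regime no tissue shows.)

**Footprints.** P-sites are sampled over CDS positions with frame weights
(0.7, 0.15, 0.15) and pause multipliers (default ×10 at the start codon's
three nucleotides, ×5 at the stop codon's); the recorded 5′ end is the
P-site minus 14 nt. RNA mode places 5′ ends uniformly over the full
transcript including UTRs.

**What the generator does not emulate.** Sequence content (no seed-match
or context scoring), read-length variation and length-dependent P-site
offsets, positional biases within libraries, isoform mixtures, batch
effects, and count correlation between the two assays beyond the shared
mean. Passing the recovery tests therefore shows that the estimators are
correct and calibrated under an idealized NB world with known truth — not
that they are robust to every artefact of real libraries.

## Numerical conventions

- All generator outputs are pure functions of (config, seed); streams for
  annotation, truth and counts are derived from the seed independently,
  so changing one stage's parameters does not scramble another's draws.
- Ties in rankings and bin borders break by gene id; sample labels are
  sorted lexicographically before clustering, so trees are invariant to
  input column order.
- Undefined quantities are flags, not errors: NaN Eff for zero RNA,
  NaN correlation for constant columns, skipped-family records, withheld
  contribution percentages, an undefined periodicity score for zero
  in-CDS reads.
- Fold-change tables serialize to TSV with full float repr; the
  decomposition identity is exact in memory and within 1 ulp after a
  decimal round trip.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the smallest sizes at which the statistical assertions have
comfortable margins: 5000 genes for classification recovery (1000
regulated), 1000 null simulations for KS calibration, 100 seeds for
periodicity under the null, 10⁵ reads for frame-fraction recovery,
200 families × 100 targets for tissue-bias recovery, 3 × 219 families for
the null false-positive rate, and 20 paired simulations for the
contribution ordering. A full run of either takes well under a minute on
one CPU; the 5000-gene pipeline demo takes a few seconds.

## Known limitations

- The 14-nt P-site offset is fixed; real libraries benefit from
  length-stratified offsets.
- The contribution estimator shares measurement error between ΔEff and
  ΔRPF (both contain the RPF term), so its percentages are comparable
  across scenarios but not an unbiased variance split.
- KS p-values on large gene sets treat genes as independent draws;
  co-regulation makes them anti-conservative, as for any gene-set shift
  test of this family.
- With only duplicates, the replicate correlation `r_rep` is itself a
  noisy ceiling; contribution percentages at low `r_rep` should not be
  over-read.
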