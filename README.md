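# translatome

Integrative analysis of paired ribosome-profiling (Ribo-seq) and RNA-seq
count data, built around the question the two assays answer together: when
the translational output of a gene changes, how much of that change comes
from mRNA abundance and how much from ribosome loading?

The package targets the paired study design common in adipocyte biology —
two differentiation lineages (brown and white preadipocytes at day 0 and
day 5) plus two adipose depots (BAT, WAT), duplicate libraries, and for
every sample both a ribosome-protected-fragment (RPF) library and an
RNA-seq library — but all operations are generic over any paired
RPF/RNA design.

## What it computes

- **Translational efficiency.** Both assays are quantified as reads per
  kilobase of coding sequence per million mapped reads (RPKM), after a
  detection filter (≥ 10 raw reads in both assays). Translational
  efficiency is the density ratio `Eff = RPKM_RPF / RPKM_RNA` —
  ribosome loading per transcript.
- **Fold-change decomposition.** Between two conditions the footprint
  change decomposes additively in log2 space,
  `log2 FC_RPF = log2 FC_RNA + log2 FC_Eff`, and genes with a large RPF
  change are partitioned into six groups — translation-driven,
  synergistic, and RNA-driven, each up or down — by the relative magnitude
  of the two components. A ratio-of-correlations estimator (replicate
  correlation as the noise ceiling) summarizes the global share of the
  translational component.
- **Metagene profiling.** Footprint 5′ ends are shifted 14 nt to the
  ribosomal P-site; per-gene normalized densities are averaged in windows
  aligned at the start and stop codons, and a 3-nt periodicity score
  (codon-frame fractions plus a chi-square test) separates genuine
  footprints from RNA-like uniform coverage.
- **Gene-set shift tests.** Cumulative-distribution (two-sample
  Kolmogorov–Smirnov) comparisons of a gene set's fold changes against the
  background, with asymptotic, exactly-enumerated (small-sample) and
  permutation p-values; plus ranked-list permutation enrichment (ES/NES)
  and the hypergeometric category test.
- **microRNA target repression.** For each seed-collapsed microRNA family,
  targets vs non-targets are compared within each tissue and across
  tissues at the RPF, RNA and Eff levels; the package reports per-family
  repression records, the fraction of families repressing more strongly in
  one tissue, and a rank-binned regression of conserved binding-site load
  on fold change.
- **Synthetic data with ground truth.** A negative-binomial generator
  plants known regulation classes, baseline efficiencies, footprint pause
  structure and per-family repression, so every stage above is testable
  with exact expectations.

## Worked example

Simulate the full six-condition design at 5000 genes and run every stage:

```bash
cat > demo.yaml <<'YAML'
outdir: demo_out
seed: 1
contrasts:
  brown:  {a: BAT_D0, b: BAT_D5, rpf_fold: 4}
  white:  {a: WAT_D0, b: WAT_D5, rpf_fold: 4}
  tissue: {a: WAT,    b: BAT,    rpf_fold: 2}
simulate:
  n_genes: 5000
YAML
translatome run --config demo.yaml
```

The run takes a few seconds and writes counts, RPKM, Eff, per-contrast
fold-change/assignment tables, KS shift tables, microRNA records and a
`report.md` that ends with:

```
## Driver classes — brown
total classified: 958
- translation_driven: 198 (20.7%)
- synergistic: 376 (39.2%)
- rna_driven: 384 (40.1%)
- Eff contribution (ratio-of-correlations): 47.8%
...
## microRNA repression
families analysed: 219
- stronger repression in BAT (RPF): 71.7% of 106 eligible families
```

Reading the numbers: of the 958 genes whose footprint output changed ≥ 4×
during simulated brown adipogenesis, 20.7% changed mainly through
translational efficiency and 39.2% through RNA and efficiency moving
together — close to the generator's planted 20/40/40 split of regulated
genes. The microRNA block recovers the planted tissue bias (75% of
families repress more strongly in BAT).

The same stages are available as library calls
(`translatome.quantify`, `.drivers`, `.metagene`, `.setshift`, `.mirna`)
and as per-stage subcommands (`translatome simulate|quantify|metagene|
classify|setshift|mirna`).

## Layout

```
src/translatome/
  simulate.py   # synthetic annotation, truth, NB counts, footprints
  quantify.py   # detection filter, RPKM, Eff, correlation, clustering
  metagene.py   # P-site shift, start/stop metagene, periodicity
  drivers.py    # fold changes, 6-group classification, contribution
  setshift.py   # ECDF, KS (asymptotic/exact/permutation), enrichment
  mirna.py      # family collapsing, repression records, site density
  pipeline.py   # end-to-end orchestration, manifest, report
  cli.py        # click command group
docs/methods.md # model assumptions, parameter choices, limitations
```
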