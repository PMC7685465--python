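# skimclone

Copy-number calling and clonal lineage tracing for cohorts of tumours
sequenced at ~1× ("skim") whole-genome coverage, plus targeted-panel (MIP)
genotyping — with a first-class synthetic-data generator so the whole
pipeline is testable without external data.

## What it does

- **depth_normalization** — 100-kb bin counts → LogR profiles against a
  panel of normals, with tangent (PCA) denoising.
- **purity** — tumour purity from read depth over lineage-fixed LOH /
  homozygous-deletion regions, from panel VAFs (median × 2), and their mean.
- **segmentation** — exact penalised least-squares piecewise-constant
  fitting (single- and multi-sample, shared breakpoints), 95%-overlap
  reconciliation, rank-test merging of adjacent segments, cross-sample
  consolidation to median breakpoints, 500-kb length filter.
- **cn_assignment** — integer (and half-integer subclonal) states via a
  Bayesian hierarchical model (Gibbs/MH over purity, ploidy and states)
  cross-validated by a Poisson model anchored on diploid segments.
- **cnv_catalogue** — cross-sample event consolidation with
  recurrence/back-mutation nomenclature (R/BM/PBM/G#CN#/L#CN#) by parsimony
  on a clade tree, linkage groups, cassette-loss (M5-style) detection with
  an opportunity-corrected Fisher test, CNV burden / genome-size records and
  their time regressions, coinfection classification.
- **breakpoint_stats** — breakpoint-reuse and CNV-clustering statistics
  against a circularised-genome permutation null.
- **mip_genotyping** — present/absent/N calls with purity- and
  contamination-aware thresholds, matrix filters, probe rebalancing, and
  allele-specific genotype fitting from VAFs.
- **synthetic_data** — clone trees with clade structure, ground-truth CNV /
  WGD / cassette events, Poisson bin counts with host-cell dilution, and
  panel reads with cross-contamination.
- **io_cli** — a YAML-configured pipeline (`skimclone run`) with
  byte-identical re-runs, plus a FASTA-coded 0/1/N character-matrix export
  for external phylogenetic tools.

## CLI

```sh
skimclone simulate --n-tips 12 --n-clades 3 --seed 17 --outdir cohort/
skimclone normalize --bin-counts cohort/bin_counts.tsv --pon cohort/pon_counts.tsv --out logr.tsv
skimclone purity --depth-windows depth.tsv --regions-bed regions.bed
skimclone run --seed 17 --outdir pipeline_out/   # full synthetic pipeline
```

All coordinates are 0-based half-open; every stochastic operation takes an
explicit integer seed.

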