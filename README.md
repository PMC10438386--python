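# landgea

**Landscape genomics: from genotypes and climate rasters to adaptive loci,
genomic offset, and seed-source matching.**

`landgea` is for population geneticists and restoration practitioners who
need to answer, from range-wide SNP data and environmental layers:

1. How is genetic variation structured across the range, and which loci are
   putatively adaptive to which environmental gradients?
2. How does adaptive variation *turn over* along those gradients, and where
   will current genotypes be most mismatched to future climate?
3. Given a planned restoration site and a future scenario, where should seed
   be sourced today?

It implements the full workflow as a reusable library plus CLI: SNP
filtering (missingness, MAF, windowed LD pruning), sparse nonnegative matrix
factorization (sNMF) for ancestry and K selection by masked cross-entropy,
latent factor mixed model (LFMM) association scans with genomic-inflation
calibration, gradient-forest (GF) allelic-turnover modelling with PCNM
spatial predictors, genomic offset across GCM × SSP × period scenarios, and
reversed-distance genomic-similarity maps for seed sourcing.  A fully seeded
synthetic-data generator (spatially structured admixture, Balding–Nichols
differentiation, planted environmental clines) makes every stage testable
against known truth.

## The statistics at the core

**Association and calibration.** For each environmental variable x, each
SNP's dosage vector y is modelled as

    y = x·b + U·vᵀ + ε,

with K latent factors U absorbing neutral structure (K chosen by sNMF
cross-entropy).  Z = b̂/se(b̂) per SNP; the genomic inflation factor

    λ = median(Z²) / χ²₁(0.5)

recalibrates the scan, P_adj = P[χ²₁ ≥ Z²/λ], and Benjamini–Hochberg
Q-values correct for multiple testing.  A SNP is putatively adaptive iff
|Z| > 2 and Q < 0.01 for at least one variable.

**Turnover and offset.** Per-SNP regression forests (500 trees) on
environmental + PCNM predictors yield R²-weighted, density-standardized
cumulative split-importance curves — allelic turnover functions F_v — per
variable.  The genomic offset of a grid cell between current environment e
and future environment e′ is the Euclidean distance in turnover space,

    offset = sqrt( Σ_v (F_v(e′_v) − F_v(e_v))² ),

min-max scaled across all scenarios of a run.  Genomic similarity maps a
restoration site's future turnover vector onto every cell's current turnover
vector and reverses the scaled distances (1 = best seed source).

## Worked example

The bundled demo simulates a 24×24 landscape with three environmental
layers, 20 localities × 8 trees, and 420 SNPs of which 20 follow a planted
logistic cline (slope 3 per s.d.) on `env1`, then runs the whole pipeline:

```bash
landgea run --demo --out demo_out
```

```
wrote 8 stage(s) to demo_out
```

Key artifacts in `demo_out/` (all plain text, with a `manifest.json` of
SHA-256 checksums):

- `filter_report.json` — `{"n_input": 420, "n_removed_missing": 0,
  "n_removed_maf": 13, "n_removed_ld": 0, "n_output": 407}`: 13 SNPs fell
  below MAF 0.01 after 5% random missingness; none exceeded the 0.2
  missingness bound or the LD r² 0.5 / 5 kb rule.
- `cross_entropy.tsv` — masked cross-entropy by K: 0.846, 0.754, 0.730,
  0.719, 0.717 for K = 1…5.  The curve drops steeply to the simulated K = 3
  then flattens; the 1% plateau rule selects K = 4 on this realization
  (classification downstream is insensitive to K = 3 vs 4).
- `lambda.tsv` — per-variable genomic inflation (env1 1.25, env2 1.05,
  env3 1.26); the calibrated P-values divide each Z² by these before
  testing.
- `gea_results.tsv` — per-SNP Z/Q/flags.  In the demo all 20 planted loci
  are flagged adaptive on `env1` and no neutral locus is flagged
  (20 true positives, 0 false positives out of 407 SNPs).
- `turnover_adaptive.json` / `turnover_neutral.json` — turnover functions;
  `env1` ranks first in R²-weighted importance for the adaptive SNP set
  (0.193, ~4× the strongest spatial eigenvector).
- `offset_mid.asc`, `offset_late.asc` — scaled genomic offset for a +0.5
  and +1.0 s.d. shift of `env1`; the `late` scenario holds the pooled
  maximum (scaled value 1).
- `similarity.asc` — seed-source similarity for the configured site under
  the `late` scenario, spanning exactly [0, 1].

The same pipeline runs from real inputs by replacing the `simulate` section
of the YAML configuration with a `paths` section (VCF, sample table TSV,
raster directories per scenario); see `landgea run --help` and
`landgea similarity --help` (restoration-site queries take `--lon/--lat`,
a scenario name, and a fitted run configuration).

## Layout

```
src/landgea/
  synthetic.py   # seeded ground-truth data generator
  genotype.py    # VCF I/O, filtering, imputation, LD pruning
  envlayers.py   # rasters (ASCII grid), extraction, pruning, PCNM
  ancestry.py    # sNMF, K selection, FST outliers
  gea.py         # LFMM Z-scores, lambda calibration, BH, classification
  forest.py      # numba regression-forest engine (split records, OOB)
  gradient.py    # turnover functions, projection, Procrustes
  offset.py      # genomic offset, scaling, contributions, similarity
  config.py      # YAML config, defaults, pipeline orchestration, manifest
  cli.py         # `landgea` command-line interface
  plots.py       # Manhattan plots, raster previews
```
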