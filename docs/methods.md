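# Methods

`landgea` re-implements, as a tested library and CLI, a range-wide landscape
genomics workflow: from filtered SNP genotypes and environmental rasters to
putatively adaptive loci, allelic-turnover maps, genomic offset under future
climate, and seed-source similarity for assisted migration.  This note
documents the models, the estimators, the defaults, and the limits of what
the synthetic experiments demonstrate.

## Synthetic data generator

The generator produces datasets with the statistical structure the analysis
stages assume, with full ground truth.

**Landscapes.** Each environmental layer is a Gaussian random field: white
noise smoothed with a Gaussian kernel (`autocorr_range` cells, default 5),
standardized to zero mean and unit variance.  Cross-layer correlation is
imposed by mixing independent fields through the Cholesky factor of the
target correlation matrix; because smoothing reduces the effective number of
independent cells, realized correlations converge on the target only as the
grid grows (the contract is ±0.15 at 100×100 with the default smoothing).
Future scenarios add a per-layer shift field; the default is +1 s.d. on the
first (temperature-like) layer, emulating directional climate change.

**Populations and admixture.** Sampling localities are distinct grid cells.
Ancestral components are placed by farthest-point sampling over the
localities, and admixture proportions are a spatial softmax of squared
distance to the component centres with kernel scale one third of the minimum
inter-centre distance — populations near a centre are dominated by its
component, intermediate populations are admixed, and the ancestry surface is
smooth in space (isolation by distance).

**Neutral loci.** Balding–Nichols: ancestral frequency p₀ ~ U(0.05, 0.95),
per-component frequencies Beta-distributed around p₀ with concentration
(1−F)/F, population frequencies the admixture mixture, individual dosages
Binomial(2, p).  Because admixture shrinks among-population variance below
the component-level F, F is calibrated at run time by bisection against a
Monte-Carlo predictor of the multilocus among-population FST (ratio of
among-population frequency variance to pooled heterozygosity, which tracks
the Weir–Cockerham estimator); the realized Weir–Cockerham FST then matches
`target_fst` (tested at 0.15 → realized ≈ 0.16 on 10 populations).

**Adaptive loci.** Population allele frequency is a logistic cline
`expit(logit(p₀) + slope · z)` in the standardized causal layer, with
p₀ ~ U(0.3, 0.7) and `slope` the effect size per environmental s.d.
SNPs are laid out on five synthetic chromosomes with ~1.2 kb geometric
spacing so windowed LD logic is exercised.  Missingness is completely at
random; real reduced-representation missingness is structured, but MCAR
suffices to exercise the 0.2 threshold.

**Not modelled:** coalescent noise, recombination, realistic LD decay,
selection through time, structured missingness, raster measurement error.
Passing tests demonstrate the estimators recover the *planted* structure
under the model's own assumptions; they say nothing about robustness to
model misspecification on real data.

## Filtering

Missingness (> 0.2 removed) → MAF on remaining calls (< 0.01 removed) →
imputation → LD pruning, in that order.  Imputation draws Binomial(2, p̂)
from the locality allele frequency (global fallback) — a frequency-based
replacement for haplotype-cluster imputation, appropriate because all
downstream statistics consume dosages only and no reference panel exists for
non-model trees.  LD pruning is a greedy left-to-right scan per chromosome:
a retained SNP removes later SNPs within 5 kb whose squared Pearson dosage
correlation exceeds 0.5 (the earlier-position SNP is kept, which makes the
result deterministic and invariant to prepending other chromosomes).
Zero-variance dosage vectors define r² = 0.

## Ancestry (sNMF) and K selection

The one-hot genotype matrix (n × 3L) is factorized as X ≈ QF with Q on the
probability simplex and an L2 sparsity weight α (default 10) on Q.  Updates
are alternating projected least squares — batched per-locus solves for F,
batched per-individual ridge solves for Q, clipping to ≥ 0 and simplex
renormalization — each followed by a backtracking step toward the previous
iterate.  Both endpoints of that segment are feasible and the loss is convex
in each factor, so the training loss is monotone non-increasing by
construction (a tested invariant).  K = 1 is computed in closed form
(Q = 1, G = global allele frequencies).

Masked cross-entropy holds out 5% of genotype entries per repetition and
scores them by the Binomial(2, QG) likelihood, where G is the ancestral
alt-allele frequency implied by F.  Per K the best of `reps` repetitions is
kept; the chosen K is the argmin unless the curve plateaus first — scanning
K upward, the first relative decrease below 1% marks the plateau and the K
before it is chosen.  The 1% tolerance makes the qualitative "plateau" rule
deterministic.

FST outliers: per SNP, FST is the mean-ancestry-weighted variance of the
ancestral frequencies over p̄(1−p̄); the statistic z² = FST·(n−K)/(1−FST)
is referred to χ² with K−1 degrees of freedom after genomic-inflation
calibration (the constant factors follow the sNMF outlier-test convention);
BH Q < 0.01 flags outliers.

## Gene–environment association

The model is Y ≈ x bᵀ + U Vᵀ + E per environmental variable.  The estimator
is deterministic ridge/least-squares rather than MCMC: latent factors are
obtained by shrinking the exposure direction of Y by
√(ridge/(ridge+σ²)) (exposure standardized, so the fit is equivariant to
affine rescaling of the variable), taking the rank-K SVD, and unshrinking
the recovered factors.  The unshrink step matters: factors from a plain PCA
of Y absorb any widespread environmental signal (destroying power when many
loci share a cline), while factors orthogonalized to x absorb too little
(inflating the null).  The default ridge of 1.0 sits on a wide plateau where
calibration, power and ranking are indistinguishable from smaller values
(tested over 1e-5…1) but the downstream regression is much better
conditioned.  Per-SNP Z-scores are OLS t-statistics of the slope in
[1, x, U]; monomorphic SNPs are assigned Z = 0.  With K = 0 the scores
reduce exactly to simple-regression t-statistics (tested to 1e-8).

Calibration: λ = median(Z²)/median(χ²₁) with the χ²₁ median computed from
the inverse CDF at run time; calibrated P = upper-tail χ²₁ probability of
Z²/λ; Q-values by Benjamini–Hochberg (statsmodels).  A SNP is putatively
adaptive for a variable iff |Z| > 2 and Q < 0.01; `adaptive_any` is the
union over variables.  λ is computed per variable.

On 10,000 null loci (structured genotypes, exposure drawn independently of
the genotype process and iid across individuals) λ averages 0.96–0.99 and
the calibrated P-values centre on 0.5; with 5% planted clines the rule
controls empirical FDR below 0.04 across 20 replicates while retaining high
power.  Two intrinsic properties of the median-based λ are worth knowing:
per-locus effective variances are heterogeneous (allele-frequency mixing),
which pulls the *median* of the null statistic a few percent below the χ²₁
median even when the test is mean-calibrated; and with a locality-level
exposure observed at only a few dozen localities this scale mixing is
stronger, pushing single-dataset λ toward ~0.93–1.0.  This is the same
mechanism behind the far-below-1 λ values reported for real range-wide
scans, and it is exactly what the λ recalibration step absorbs before
P-values are formed.

## Gradient forest

Per SNP, allele frequency (dosage/2 at the sampled individuals) is regressed
on the environmental variables plus PCNM spatial eigenvectors with a
500-tree bootstrap regression forest (mtry = ⌈p/3⌉, minimum leaf 2 so every
partition keeps at least two points, depth otherwise uncontrolled).  The
forest engine is numba-compiled because the stage needs ~10⁵ small trees per
dataset *and* the raw split records of every tree; it reproduces sklearn's
out-of-bag R² on common fits (tested) at ~5× the speed for this workload.

PCNM: pairwise site distances truncated at the longest minimum-spanning-tree
edge (replacement value 4× truncation, the method's original constant),
double-centred and eigen-decomposed; of the positive-eigenvalue vectors the
largest-eigenvalue half (broadest spatial scales) is kept.  For projection
onto rasters, the site eigenvectors are interpolated by inverse-distance
weighting — spatial eigenvectors have no analytic off-site values, and IDW
reproduces site values exactly while decaying smoothly.

Per-variable credit uses permutation importance on out-of-bag samples
(estimated on a 150-tree subsample; Breiman-style, one permutation per
tree).  For predictors correlated above |r| = 0.5 the permutation is
stratified within quantile bins of the partners — a cluster-conditional
stand-in for full conditional permutation that removes most spurious credit
sharing at desk scale.  A SNP with OOB R² ≤ 0 is excluded.  Its R² is
distributed over variables proportional to (clipped) importance, and its
split improvements along each variable are scaled to that share, divided by
the per-bin data density (bin count derived from the log₂(0.368·p)/2
binning control, minimum 2), and accumulated into the cumulative turnover
function: non-decreasing, zero at the predictor minimum, total height equal
to the variable's R²-weighted importance.  Projection evaluates the turnover
functions by linear interpolation between split knots, clamped outside the
training range; PCA (PC1–PC3, deterministic sign convention) summarizes the
turnover space, and orthogonal Procrustes superposition (translation,
rotation/reflection, isotropic scaling) of neutral onto adaptive scores
yields per-cell residuals mapping where adaptive structure departs from the
neutral expectation.

Because feature subsampling depends on predictor column order, importances
are order-invariant in distribution and in ranking, not bitwise.

## Genomic offset and similarity

Offset per cell is the Euclidean distance between future and current
turnover vectors over the p predictors.  The named metric (with the square
root) is the default; `sqrt=False` preserves the raw sum of squares — the
two are monotonically related, so rankings and scaled maps are unaffected.
Offsets are min-max scaled jointly across every scenario of a run (never per
map), GCM members can be averaged per SSP × period, and per-variable
contributions are the squared-difference shares (undefined, NaN, where the
offset is zero).

The similarity map transforms the restoration site's *future* predictor
vector through the turnover model and compares it against every cell's
*current* turnover vector; distances are min-max scaled over the mask and
reversed, so 1 marks the best-matched candidate seed source.  The opposite
direction (site current vs. landscape future) can be obtained by swapping
the stack arguments.

## Pipeline and reproducibility

A single YAML configuration drives filter → env/PCNM → structure → GEA →
gradient forests (adaptive and neutral sets, the neutral set being all
filtered SNPs not classified adaptive) → projection/Procrustes → offset →
optional similarity.  Defaults are the workflow's stated values (missingness
0.2, MAF 0.01, LD r² 0.5 in 5 kb, K 1–15 × 10 repetitions, 500 trees,
|Z| > 2, Q < 0.01).  Every stage writes its artifacts with SHA-256 checksums
into a JSON manifest and derives its seed from the run seed, so a rerun with
the same configuration reproduces identical checksums (a tested contract).
Rasters are read and written as headered ESRI ASCII grids — a plain-text
format sufficient for the single planar grid the pipeline assumes.

### Problem sizes in the test suite

The bundled experiments use desk-scale designs chosen to make the targeted
effects detectable with comfortable margins: null calibration on 10,000 loci
× 200 individuals; FDR over 20 replicates of 600 loci with 5% planted
clines at slope 3; structure recovery on 3 populations × 20 individuals ×
1,000 loci over 10 replicate datasets; association power with a single
slope-2 cline among 500 neutral loci over 10 replicates; gradient-forest
causality at 30 localities × 10 individuals, 200 SNPs, 500 trees over 10
replicates.  The demo pipeline uses a 24×24 landscape, 20 localities × 8
individuals and 420 SNPs.

## Known limitations

- The association estimator is the deterministic ridge formulation; the
  MCMC variant it replaces explores posterior uncertainty that is not
  represented here (repetitions of the deterministic fit are identical).
- Conditional permutation importance is approximated by stratified
  permutation within correlated clusters; with many strongly collinear
  predictors some credit sharing remains.
- The plateau rule for K and the 1% tolerance are a deterministic reading of
  a qualitative criterion; curves that keep decreasing slowly select the
  argmin.
- PCNM projection by IDW is an interpolation convenience, not a model of
  spatial process beyond the sampled sites; similarity and offset maps far
  from any sampling site inherit that extrapolation.
- A single planar coordinate system is assumed; great-circle geometry and
  map reprojection beyond one grid are out of scope.
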