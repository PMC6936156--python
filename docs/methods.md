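# Methods

## Problem and model

A bulk tumor sample with tumor-cell fraction (purity) *p* yields, at CpG
site *i*, an observed methylation level

    beta_i  ≈  p · mu_tumor,i + (1 − p) · mu_normal,i ,

a convex mixture of the pure-tumor and contaminating-normal methylation
levels. At a site that is near-fully methylated in tumor cells and
near-unmethylated in normal tissue (mu_tumor ≈ 1, mu_normal ≈ 0), beta_i is
approximately *p* itself; a mirror-image hypo-methylated site gives
1 − beta_i ≈ p. The estimator therefore (1) hunts for such *informative*
sites in a paired tumor/normal cohort, and (2) reads each tumor sample's
purity off the consensus of its transformed beta values at those sites.

## Stage 1: site scoring and selection

**Per-site tests.** The two-sided paired T test captures a mean shift
between tumor and matched normal; a one-sided F test (tumor variance over
normal variance, upper tail) captures increased tumor variability, which is
itself a purity-driven signal — samples with different purities scatter the
tumor betas at an informative site while the normals stay tight. Both
p-values become non-negative normal-quantile signals, m = max(0, Φ⁻¹(1−p_m))
and v = max(0, Φ⁻¹(1−p_v)), computed through the normal inverse survival
function so p down to 1e−320 survives without underflowing through 1 − p.
Signals at p ≥ 0.5 clamp to zero; a site with both signals zero, zero
variance of the paired differences, or zero normal variance is *untestable*
and excluded from everything downstream (no fatal error — degenerate sites
are a data property, not a bug).

**Signal combination.** The combined score is
S = sign(T)·(λv + (1−λ)m) with λ = v/(m+v): the weight goes to the *larger*
signal, so two equal signals of 14.9 combine to 14.9 and a pure variance
signal of 38 stays 38. The alternative pairing that applies λ to the mean
signal (which would annihilate a pure variance signal) is available as
`lambda_pairing="literal"` for comparison only. No multiple-testing
correction is applied anywhere: sites are *ranked* by score magnitude, never
thresholded by adjusted p.

**Neighbor correction.** Methylation of CpGs within ~1 kb is strongly
correlated, so each testable site's score is corrected by its two nearest
testable neighbors on the same chromosome within a *strict* 1000-bp window
(a site exactly 1000 bp away contributes nothing):
f_S = S + Σ α·S_n with α = 1 − d/1000. Only testable sites may donate
influence — letting null sites donate, or summing over *all* in-window
sites (available as `neighbor_mode="all_in_window"`), tends to promote
sites that are not themselves differentially methylated. A neighbor donates
its *base* score, not its own corrected score; influence does not propagate
recursively. Equidistant neighbor ties break by ascending position.

**Selection.** The top k = 1000 sites by |f_S| are kept. Magnitude ranking
(rather than signed) is deliberate: hypo-methylated sites carry negative
scores by the sign convention yet are equally informative, and the purity
stage uses both directions; `ranking="signed"` is kept selectable. All
ranking ties break by (chromosome, position) so runs are deterministic.
Direction labels (hyper/hypo) come from the sign of the paired-T statistic;
a mean-normal-beta-vs-0.5 classifier was considered and rejected as primary
because the T sign is what defines the score's direction in the first
place.

Two baselines with the same interface support comparisons: ranking by
paired-T p alone, and an F-test filter (p < 0.05) followed by paired-T
ranking.

## Stage 2: purity estimation

Per tumor sample, informative-site betas transform as hyper → β,
hypo → 1 − β (an involution), and a Gaussian KDE is fitted to the
transformed values. The purity is the argmax of the density on a fixed
uniform grid of 1001 points over [0, 1] (resolution 0.001, ties toward the
lower grid point — deterministic by construction). Bandwidth defaults to
the Silverman normal-reference rule; a fixed numeric kernel standard
deviation may be supplied instead. No boundary correction is applied at
0/1; restricting the grid to [0, 1] is the only domain handling. A sample
whose values are all identical bypasses the KDE and returns that value; a
sample with fewer than `min_sites` (default 10) usable values is flagged
with a NaN purity rather than aborting the cohort.

## Input handling

Beta matrices (TSV/CSV, sites × samples) must lie in [0, 1]; annotations
come as 3-column TSV (1-based positions) or 4-column BED (0-based
half-open, converted to 1-based points on read — one internal coordinate
convention keeps distance arithmetic trivial). QC drops unannotated sites,
sex-chromosome sites (chrX/chrY/X/Y, case-insensitive; optional) and sites
missing in more than `max_missing_fraction` (default 0.2) of samples.
Pairing is complete-case per site: any site missing a value in either
member of any pair is dropped, because paired tests need complete pairs and
imputation would add unstated modelling. Patients lacking one of their two
samples are skipped with a warning; a design row naming a sample absent
from the matrix is an error.

## Synthetic cohorts

The generator draws, per site, Beta-distributed betas parameterised by
(mean, precision κ): a = μκ, b = (1−μ)κ, so one knob (κ, default 150,
beta sd ≈ 0.04 at μ = 0.5) sets the measurement noise on the natural [0, 1]
support. Background sites share one mean (uniform on (0.1, 0.9), spanning
the plausible array range) between tumor and normal. Informative hyper
sites draw μ_normal ~ U(0.02, 0.08) and μ_tumor ~ U(0.92, 0.98), hypo sites
the mirror image: informative sites are *defined* by near-boundary
methylation in the two compartments — that is precisely what makes the
mixture value readable as purity — so the generator places them there;
widening these ranges degrades every estimator that reads the mixture
directly, not just this one. Tumor betas center on the purity mixture
p·μ_tumor + (1−p)·μ_normal with per-patient purity p ~ U(0.3, 0.9) by
default (explicit purity lists are accepted).

Sites live on two synthetic 10-Mb chromosomes. Half of the informative
sites (configurable `cluster_fraction`) come in pairs 100–900 bp apart to
exercise the neighbor correction including the strict window; the other
half, and all background sites, sit ≥ 2000 bp from any informative site so
isolated-site behaviour is also covered. Informative anchors occupy a
3000-bp lattice sampled without replacement; infeasible configurations
(more units than lattice anchors) error out. With `common_noise=True` a
single uniform deviate per site drives every patient's tumor draw through
the Beta quantile function, so tumor columns differ only through purity —
the device behind the strict purity-monotonicity test.

Defaults (30 patients, 20,000 sites, 500 + 500 informative, κ = 150,
cluster fraction 0.5, seed 2019) run the full pipeline in about a second
and are the conditions under which the recovery (MAE ≤ 0.05), monotonicity
and ≥ 90% selection-enrichment checks are asserted.

**What the generator does not emulate:** real 450K probe geography and
CpG-island structure, copy-number-driven beta distortion, cell-type
heterogeneity beyond a single normal compartment, batch effects, and
probe-level artifacts (SNPs, cross-reactivity). Passing tests demonstrate
correctness of the algorithm under its own mixture model, not field
performance on TCGA-scale data.

## Numerical choices

- p-values: scipy's Student-t/F survival functions; signals via
  `norm.isf(p)` (never `ppf(1-p)`), clamped at 0.
- Exact zero variance (differences or normals) → untestable, not ±inf.
- Neighbor search: per-chromosome sorted positions + binary search;
  agreement with a brute-force all-pairs implementation is asserted
  exactly, not approximately.
- KDE: scipy `gaussian_kde`; a numeric bandwidth b is converted to scipy's
  factor b/sd(values) so b is the kernel sd itself.
- All tie-breaks (neighbor equidistance, ranking, grid argmax) are
  deterministic and documented above.

## Known limitations

- The score has no null calibration across cohort sizes: quantile signals
  grow with n, so k-site selections, not score thresholds, are comparable
  across cohorts.
- The KDE mode ignores multimodality beyond picking the global mode; a
  heavily subclonal sample can pull the mode away from the dominant clone's
  purity.
- Purity near 0 or 1 is biased inward slightly because informative-site
  means are not exactly 0/1 and the KDE has no boundary correction.
- Baseline selectors share stage 2; differences between selectors reflect
  site choice only.
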