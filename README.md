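# peis — tumor purity from paired tumor/normal DNA methylation

Bulk tumor samples are mixtures: tumor cells blended with adjacent normal,
stromal and infiltrating immune cells. The tumor-cell fraction — the
**tumor purity** — confounds every downstream analysis of bulk methylation
data, so estimating it per sample matters. `peis` implements a purity
estimator for paired tumor/normal Illumina-450K-style beta-value cohorts:
it selects *informative* CpG sites by an integrated mean/variance signal
score corrected for correlation among adjacent sites, then reads each tumor
sample's purity off the mode of a Gaussian kernel density over transformed
beta values at those sites.

## Method

**Stage 1 — informative-site selection.** For every CpG site *i* a
two-sided paired T test (tumor vs matched normal means) and a one-sided F
test (tumor variance exceeding normal variance) give p-values
*p*<sub>m</sub> and *p*<sub>v</sub>, mapped to normal-quantile signals
*m* = max(0, Φ⁻¹(1 − *p*<sub>m</sub>)) and
*v* = max(0, Φ⁻¹(1 − *p*<sub>v</sub>)). They merge into one signed score

&nbsp;&nbsp;&nbsp;&nbsp;*S*<sub>i</sub> = sign(*T*) · (λ*v* + (1 − λ)*m*),&nbsp;&nbsp;λ = *v* / (*m* + *v*),

a convex combination weighted toward the larger signal (both signals at
p = 1e−50 score 14.9; a clamped mean signal with p<sub>v</sub> = 1e−320
scores 38). Positive scores mark hyper-methylated sites, negative
hypo-methylated; sites with both signals zero (both p ≥ 0.5) are dropped.
Because adjacent CpGs are strongly correlated, each score is then corrected
by its two nearest testable neighbors within a strict 1000-bp window,

&nbsp;&nbsp;&nbsp;&nbsp;*f*<sub>S<sub>i</sub></sub> = *S*<sub>i</sub> + Σ<sub>n≤2</sub> α<sub>n</sub>·*S*<sub>i<sub>n</sub></sub>,&nbsp;&nbsp;α = 1 − distance/1000,

and the top 1000 sites by |*f*<sub>S</sub>| form the informative set.

**Stage 2 — purity.** In each tumor sample, informative-site beta values
are put on a common scale (hyper: β, hypo: 1 − β); since informative sites
are near-fully methylated in pure tumor and near-unmethylated in normal
(or vice versa), the transformed values pile up around the tumor-cell
fraction. The purity estimate is the argmax of a Gaussian KDE (Silverman
bandwidth) evaluated on a 1001-point grid over [0, 1].

T-test-only and F-then-T baseline selectors are included for comparison,
and a synthetic-cohort generator with known truth makes the whole pipeline
testable without any external downloads.

## Worked example

```python
from peis import PeisModel, evaluate_recovery, simulate_cohort

cohort = simulate_cohort(seed=2019)          # 30 patients, 20,000 sites
model = PeisModel(cohort.beta, cohort.annotation, cohort.design)
res = model.fit()
print(res.summary())                          # header lines below
rec = evaluate_recovery(res.purity, cohort.truth)
print(f"MAE = {rec['mae']:.3f}, bias = {rec['bias']:.3f}")
```

```
PEIS tumor-purity estimation
============================================================
Patients (pairs):        30
Sites tested:            20000
Sites testable:          15200
Selector:                peis
Informative sites (k):   1000
  hyper-methylated:      509
  hypo-methylated:       491
Neighbor window:         1000 bp (two_nearest)
KDE bandwidth:           silverman
------------------------------------------------------------
Purity: mean 0.579  median 0.589  range [0.339, 0.860]  (n = 30)
...
MAE = 0.017, bias = -0.009
```

20,000 simulated sites (1000 truly informative) are scored, 15,200 carry a
nonzero signal, and the top 1000 by neighbor-corrected score are kept; the
per-sample KDE modes recover the simulated purities with a mean absolute
error of 0.017. The same workflow runs from the shell:

```bash
peis simulate --out cohort/ --seed 2019
peis run --beta cohort/beta.tsv --annotation cohort/annotation.tsv \
         --design cohort/design.tsv --outdir results/
```

`peis select-sites` and `peis estimate-purity` expose the two stages
separately; see `docs/methods.md` for the model details and tunables.

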