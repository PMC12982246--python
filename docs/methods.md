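# Methods

`dusgp` implements a genomic-prediction framework for DUS (Distinctness,
Uniformity, Stability) variety testing in crops where quantitative
characteristics are assessed in multi-year or multi-country trials. This
note documents the statistical models, the numerical choices, what the
synthetic-data generator emulates, and the design decisions taken where
several reasonable options existed.

## Data model

Genotypes are per-variety **allele frequencies**, not individual genotypes.
For pooled genotyping-by-sequencing of outbreeding varieties (e.g. perennial
ryegrass, where a variety is a population), the natural datum at a site is
the non-reference read fraction; for array data on inbred material
(e.g. wheat) the alternate-allele dosage divided by ploidy plays the same
role. Frequencies live in [0, 1] regardless of ploidy, which is what lets
diploid and tetraploid varieties share one analysis.

Phenotypes are long-format trial records `(variety, environment, group,
characteristic, value)`. The **ryegrass layout** reads environments as
years and groups as ploidy levels (one trial-mean record per variety-year);
the **wheat layout** reads environments and groups as countries, with a
single 1–9 note per variety-country.

## Genomic relationship matrix

With frequency matrix `F` (varieties × markers), columns are centred on
their across-variety means, missing cells imputed to the mean (centred
value 0 — no information), and

```
G = W W' / c,   W = F − colmean(F),   c = Σ_m s²_m,
```

where `s²_m` is the empirical sample variance (divisor n−1) of the
frequencies at marker `m`. The empirical scaling is the non-parametric
analogue of the usual `Σ 2 p_m (1 − p_m)` denominator; it requires no
ploidy-specific constant, so mixed-ploidy panels pose no problem, and it
makes the mean diagonal of `G` close to 1 under exchangeable varieties.
Markers missing in more than 10% of varieties, or with (numerically) zero
variance, are excluded and logged. `G` built this way is always singular
(column centring gives `G·1 = 0`); if rounding drives the smallest
eigenvalue below −1e-8, a minimal diagonal ridge `|λ_min| + 1e-6` is added
and recorded. Centring uses global (not per-ploidy-group) means.

Rogers' distance reduces, for biallelic frequencies, to the mean absolute
frequency difference over the markers observed in both varieties (pairwise
deletion). Phenotypic distance is Euclidean over per-variety characteristic
means scaled by their across-variety standard deviation; the correlation of
the two distances (upper triangles, Pearson) is the quantity that decides
whether a plain distance threshold could manage a reference collection.

## REML engine

All models are Gaussian linear mixed models

```
y = X b + Σ_r Z_r u_r + e,   u_r ~ N(0, σ²_r K_r),   e ~ N(0, σ²_e I),
```

with `K_r` the identity or the GRM (at most one GRM term). The restricted
log-likelihood is maximised over log-variance components with L-BFGS-B and
the analytic gradient; all quantities are computed through Henderson's
mixed-model equations rather than the dense observation covariance. Each
GRM term is absorbed as `u = L a` with `K = L L'` an eigenvalue square root
truncated at a relative eigenvalue of 1e-10, so every transformed effect
has identity covariance, the coefficient matrix stays `(p+q) × (p+q)`, and
exactly singular GRMs are handled without modification. Cross-products are
precomputed once per fit, making each likelihood evaluation O((p+q)³)
regardless of the number of records.

Numerical choices: initialisation splits the response variance equally over
components (scale-free, deterministic); bounds on log components are
`[log(1e-8 · var y), log(1e6 · var y)]`, and a component at the lower bound
is reported as pinned (effectively zero — REML with a non-negativity
constraint); convergence uses scipy's `ftol=1e-13, gtol=1e-9` with a
Nelder–Mead polish if line search fails; fixed effects use treatment coding
with the first level as reference, and aliased columns are dropped
deterministically in column order by incremental Gram–Schmidt. The engine
is validated against a dense-covariance grid-search oracle in the tests.

Prediction-error covariances come from the inverse coefficient matrix:
`var(û_i − û_j − (u_i − u_j)) = C_ii + C_jj − 2 C_ij`, mapped through `L`
for GRM terms. Contrasts that involve fixed covariates (gBLUP+QTL) use the
joint (b̂, û) error covariance, so the covariate estimation error and its
correlation with the BLUPs are fully propagated into the SED.

All tests use the normal approximation to the t test (`z = |est|/sed`,
two-sided): contrast degrees of freedom in these layouts exceed 100, where
the approximation is excellent. At the LSD boundary the decision is made on
the z scale with a 1e-12 relative tolerance so that a difference exactly
equal to the threshold counts as distinct.

## Model layouts

Per characteristic:

* **ryegrass**: fixed ploidy (+ optional centred QTL frequency covariates);
  random variety (GRM for gBLUP/COYD-GP, identity for COYD), year, and
  year-by-ploidy; the residual is the variety-by-year interaction.
* **wheat**: intercept (+ QTL covariates); random variety (GRM) and
  country; with one record per variety-country the variety-by-country
  interaction is inseparable from the residual and is absorbed there
  (recorded in fit metadata).

Comparisons never cross ploidy groups (ryegrass) or countries (wheat).

## Distinctness tests

**COYD (long-term)** fits the ryegrass layout with an identity-covariance
variety effect on all available years and compares each within-group pair
difference to

```
LSD = z_{1−α/2} · sqrt(2 σ̂²_ε / k),   k = 3 years by default, α = 0.01,
```

using only the residual (variety-by-year) component: year and
year-by-ploidy effects cancel in within-group over-years differences. The
boundary counts as distinct. **COYD-GP** is the identical model and
decision rule with GRM-structured variety covariance — the genomic
information sharpens the estimated variety differences and that is the only
change; with an identity GRM it reproduces COYD exactly (regression-tested
bit-for-bit on decisions). An alternative rule comparing each difference to
its own prediction-error SED is available via `rule='sed'`.

The **wheat** standard is non-model-based: a pair is distinct when its
notes differ by at least 2 (configurable) in a shared country.

**Collation** across characteristics is an OR of decisions (distinctness in
a single characteristic suffices) with the element-wise minimum p-value
reported, not re-thresholded.

## Reference-collection management

`crossvalidate` runs the leave-one-out candidate scheme: each variety's
phenotype records are masked, the model refitted (variance components
re-estimated per fold by default; `reuse_vc` reuses full-data components,
agreeing within a few percent and much faster), and its differences from
every within-group known predicted and tested at α. Masking removes
records only — the candidate stays in the GRM, which is its only
information channel; a test perturbs masked records and asserts identical
predictions. Pairs are counted as ordered (candidate, known) within groups.
The truth standard per pair is long-term COYD (ryegrass) or the two-note
rule (wheat). R² is the squared Pearson correlation between predicted and
observed pair differences, with "observed" the difference of raw
over-environment variety means; computing it on variety means instead of
pair differences would be the main alternative.

`simulate_reduction` draws m-variety candidate sets and reports the mean
fraction of remaining varieties distinct from all m candidates — the share
of the reference collection that would not need planting. Enumeration is
exact when `C(n, m) ≤ 10,000`, otherwise seeded Monte-Carlo with `n_sim`
(default 1000) samples and a reported MC standard error. The exact curve is
non-increasing in m.

## GWAS

Variance components are estimated once under the null model and held fixed
across markers (the standard two-stage approximation); each marker is a
Wald z test of its fixed effect under GLS with the null covariance, which
is algebraically exact at fixed components and is checked against a dense
GLS oracle at 1e-8. Thresholds: Bonferroni at a family-wise 0.05 over
tested markers, and Benjamini–Hochberg FDR at q = 0.05. Forward selection
adds the most significant passing marker as a fixed covariate, re-estimates
the null, rescans, and caps selection at one marker per chromosome. A
relaxation factor on the Bonferroni limit is exposed for expert use
(sub-threshold candidates are a judgement call, not an algorithm); the
default is strict. Population structure is handled by the kinship term
only (K model); principal-component fixed effects are not added, since the
GRM term subsumes the structure the PCs would capture in these panels.

## Synthetic data: what it emulates, and what it does not

Variety pools are simulated directly as Beta-distributed allele
frequencies: founder frequency `p ~ U(0.05, 0.95)` per marker, variety
frequency `~ Beta(p·ν, (1−p)·ν)` with `ν = (1−d)/d`, so the across-variety
variance is `d·p(1−p)` and `d` acts as an Fst-like differentiation. Two
structural features of real reference collections are first-class options
because the method comparisons hinge on them:

* **Families.** Real collections contain related varieties from the same
  breeding programmes. A two-level Beta hierarchy (families share a
  family-level frequency profile; families share ploidy) produces
  within-family relationships around 0.6 at the default settings. Without
  this, all varieties are exchangeable, GRM off-diagonals are pure sampling
  noise, and genomic covariance has nothing to contribute — COYD-GP then
  ties with COYD to within noise, and candidate prediction is impossible.
* **Historical unbalance.** DUS trials run a few years per variety within a
  long period. `years_per_variety` restricts each variety to a contiguous,
  randomly placed window of trial years. With complete balanced data the
  phenotypic information per variety is so high that the genomic term is
  nearly redundant.

Traits are polygenic (`u ~ N(0, σ²_poly G)` using the panel's own GRM) plus
optional planted QTLs (`qtl_effect_for_fraction` sizes an effect to a
target share of genetic variance), with Gaussian year, year-by-ploidy and
residual effects; wheat notes are rank-binned into nine equal-frequency
bins. Not emulated: linkage disequilibrium beyond chromosome-block
assignment, selection or pedigree dynamics, read-level sequencing noise,
genotype-by-environment covariance beyond the fitted terms, and non-Gaussian
trait distributions. Passing tests therefore demonstrate correctness and
calibration of the machinery under the stated model, and the *direction* of
the method differences under realistic relatedness and unbalance — not
performance figures transferable to any particular real crop panel.

`default_benchmark` fixes the package's reference study conditions: 200
varieties in families of 5 (d between 0.25, within 0.20), half tetraploid,
1000 markers on 7 chromosomes, 3 characteristics, 10 years with 3-year
windows, components σ²_variety=1.0, σ²_year=0.5, σ²_year×ploidy=0.25,
σ²_residual=1.0 (per-year heritability 0.5). Evaluation scripts use panels
of 60–300 varieties and 300–2000 markers so everything runs in minutes on
one CPU; those sizes are stated in each test.

## Calibration of the candidate test

The candidate-vs-known test declares distinctness when `|δ̂|/sed` exceeds
the 1% normal quantile. Its advertised guarantee is that the
**prediction-error pivot** `(δ̂ − δ_true)/sed` is standard normal; the
package checks this on simulated data where `δ_true` is known, requiring
the 1% exceedance rate over ≥10,000 leave-one-out candidate/known pairs to
lie in [0.005, 0.02] (component estimation adds a little noise to the
nominal rate). A literal null — pairs whose true genetic values are made
exactly equal — is *not* a useful calibration target for BLUP-based tests:
conditional on a zero true difference the statistic has variance
`1 − sed²/v₀ < 1`, so the test is strictly conservative on such pairs by
construction (and degenerate for genomic clones, where sed = 0). The same
argument applies to COYD under shrinkage, whose LSD is referenced to
unshrunken k-year means; its literal-null error rate is bounded above by
the nominal level rather than matching it.

## Known limitations

* Ordinal notes are treated as continuous; cumulative-link models are out
  of scope.
* The REML engine targets the dense-MME regime (up to a few thousand
  records and a few hundred random-effect levels per fit); it does not
  exploit sparsity for very large trials.
* Uniformity and stability testing (COYU etc.) are not implemented.
* The wheat layout assumes one note per variety-country; replicated
  within-country data must use the ryegrass layout.
* VCF ingestion takes the first ALT allele of biallelic sites only;
  multi-allelic sites are rejected with a report.
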