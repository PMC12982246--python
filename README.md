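# dusgp — genomic prediction for DUS variety testing

Plant variety protection requires every candidate variety to be shown
**D**istinct from all varieties of common knowledge, **U**niform and
**S**table, in growing trials run over several years. As reference
collections grow, trialling every candidate against every known variety
becomes the dominant cost. `dusgp` implements a genomic-prediction
framework for two tasks faced by DUS testing organisations working on
quantitative characteristics:

* **Reference-collection management** — predict, from genome-wide markers
  alone, the per-characteristic difference between a *candidate* variety
  (genotype only) and each *known* variety (genotype + trial history), and
  test each predicted difference so that knowns confidently distinct from
  all candidates need not be planted.
* **COYD-GP distinctness testing** — augment the established
  combined-over-years distinctness test (COYD) with a genomic relationship
  matrix on the variety effect, sharpening the estimated variety
  differences when both members of a pair have trial data.

The package targets pooled-genotyping crops: genotypes are per-variety
allele frequencies (non-reference read fractions), which makes mixed
diploid/tetraploid panels (e.g. perennial ryegrass) and array-genotyped
inbreds (e.g. wheat) fit one data model.

## The models

With `y` the trial means of one characteristic, the gBLUP layout for
multi-year data is

```
y = Xb + Z_v u + Z_y t + Z_yp w + e,
u ~ N(0, σ²_v G),  t ~ N(0, σ²_y I),  w ~ N(0, σ²_yp I),  e ~ N(0, σ²_ε I),
```

with fixed ploidy effect `b`, and `G` the VanRaden-style genomic
relationship matrix adapted to allele frequencies:
`G = WW′/c` with `W` the column-centred frequency matrix and
`c = Σ_m s²_m` the summed empirical per-marker sampling variance — a
scaling that needs no ploidy-specific constant. Variance components are
estimated by REML (a from-scratch engine built on Henderson's mixed-model
equations; see `docs/methods.md`). A candidate's predicted difference from
a known is the BLUP contrast `û_c − û_k` (plus fixed QTL-covariate terms
for gBLUP+QTL), tested with the normal approximation
`z = |δ̂|/sed, sed² = C_cc + C_kk − 2C_ck` at α = 0.01.

COYD compares within-ploidy variety-effect differences against
`LSD = z_{0.995}·sqrt(2σ̂²_ε/3)`; COYD-GP is the same test with
GRM-structured variety covariance. Single-marker GWAS with the GRM as
polygenic background, Bonferroni/FDR thresholds and per-chromosome forward
selection supplies QTL covariates. A synthetic-data module simulates both
study layouts (family-structured frequency panels, historical-style
unbalanced trials) with known truth.

## Worked example

```python
from dusgp import RunConfig, build_grm, coyd, coyd_gp, crossvalidate
from dusgp.gblup import LayoutSpec
from dusgp.refmanage import simulate_reduction
from dusgp.distinctness import collate
from dusgp.synthdata import default_benchmark

panel, trials, truth = default_benchmark(seed=1, n_varieties=80,
                                         n_characteristics=2)
grm = build_grm(panel)
print(f"GRM: {grm.n} varieties, scaling constant c = {grm.scaling_constant:.2f}, "
      f"mean diagonal = {grm.values.diagonal().mean():.3f}")

cfg = RunConfig(seed=1)          # alpha = 0.01, LSD at k = 3 years
for ch in trials.characteristics:
    a = coyd(trials, ch, cfg)
    b = coyd_gp(trials, None, ch, cfg, grm=grm)
    print(f"{ch}: COYD {100 * a.distinct_proportion():.1f}% distinct, "
          f"COYD-GP {100 * b.distinct_proportion():.1f}%")

report = crossvalidate(panel, trials, LayoutSpec("ryegrass"), cfg)
print(report.per_characteristic.round(3).to_string(index=False))

overall = collate([report.cv_matrices[c] for c in sorted(report.cv_matrices)])
red = simulate_reduction(overall, [1, 3, 5], cfg)
for r in red.table.itertuples(index=False):
    print(f"m={r.m} candidates: {100 * r.proportion:.1f}% of knowns "
          f"need not be planted")
```

prints

```
GRM: 80 varieties, scaling constant c = 70.91, mean diagonal = 0.988
trait_1: COYD 3.8% distinct, COYD-GP 4.8%
trait_2: COYD 4.7% distinct, COYD-GP 5.1%
characteristic  prop_cv  prop_truth    r2  n_pairs
       trait_1    0.032       0.038 0.407     3120
       trait_2    0.030       0.047 0.464     3120
m=1 candidates: 5.3% of knowns need not be planted
m=3 candidates: 0.0% of knowns need not be planted
m=5 candidates: 0.0% of knowns need not be planted
```

Reading the output: the empirically scaled GRM has unit-scale diagonal;
COYD-GP finds more distinct pairs than COYD for every characteristic
(genomic covariance sharpens the variety-effect estimates); leave-one-out
genomic prediction (`prop_cv`) is more conservative than full-data COYD
(`prop_truth`) because candidates contribute no trial data, and the R²
columns give the squared correlation between predicted and observed pair
differences. The reduction curve converts the collated decisions into the
share of the reference collection that would not need planting for a given
number of simultaneous candidates.

The same pipeline is scriptable from the shell:

```
dusgp --seed 3 simulate --out-dir runs/demo --n-varieties 100
dusgp grm runs/demo/genotypes.csv --out-dir runs/demo
dusgp coydgp runs/demo/genotypes.csv runs/demo/trials.csv --out-dir runs/demo
dusgp crossval runs/demo/genotypes.csv runs/demo/trials.csv --out-dir runs/demo
```

Each subcommand writes CSV results plus a JSON manifest (config echo,
derived seed, input checksums) sufficient to reproduce the run.

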