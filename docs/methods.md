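# Methods

This note records the statistical model, the algorithmic and numerical
choices, what the synthetic generator does and does not emulate, and the
known limitations. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## The weighted animal model

Per trait and per class factor (SNP genotype or pooled diplotype) we fit

    y = X b + Z a + e,    a ~ N(0, A σ²_a),    e ~ N(0, W σ²_e)

* `y`: EBVs of the phenotyped cows (kg for MY/FY/PY, percentage points for
  FP/PP). EBVs arrive pre-adjusted for environment, so the fixed part is
  mean + class only; extra covariates can be added through the design but
  default to none.
* `A`: numerator relationship matrix over the pedigree, trimmed to a
  configurable number of ancestral generations above the phenotyped animals
  (default 3). Built by the tabular method — the model needs `A` itself, not
  `A⁻¹`, so Henderson's inverse rules buy nothing here. Unknown parents are
  unrelated non-inbred founders; identifiers compare as exact strings.
* `W = diag(1/REL_i)`: an EBV with reliability 0.5 carries twice the residual
  variance of a perfectly reliable one.

### REML

With one record per animal, `Z` restricted to phenotyped animals gives
`V = σ²_e (λ A + W)`, `λ = σ²_a/σ²_e`. We maximise the restricted
log-likelihood by **exact 1-D profiling**: at any `λ`, `σ̂²_e` has a closed
form and `b̂` is GLS, so a bounded scalar search over `log λ`
(`scipy.optimize.minimize_scalar`, tolerance 1e-8, bounds 1e-6..1e4) plus an
explicit check of the `λ = 0` boundary finds the optimum. This replaces the
usual EM-REML/AI iteration: with a single variance ratio the profile is exact,
needs no step-halving heuristics, and cannot decrease the objective. Each
likelihood evaluation is one Cholesky of `λA + W` (O(n³), n ≈ 500 →
milliseconds).

By default variance components are re-estimated per trait × per marker;
`fixed_lambda` lets a caller estimate once per trait and reuse.

### Tests and reports

* Overall class test: Wald F on the class-difference contrasts,
  `num_df = k − 1`, `den_df = n − rank(X)` (residual-style; no Satterthwaite).
* Least-squares means: estimable `μ + class_k` rows; reference class =
  lexicographically last (irrelevant to estimable quantities, fixed for
  reproducibility).
* Pairwise letters: all pairwise t-tests on LSM differences, insert-and-absorb
  compact letter display; lowercase at 0.05, uppercase at 0.01.
* Bonferroni: `m` defaults to the number of genotyped markers (6 for the
  default panel → thresholds 0.0083 / 0.0017), not markers × traits;
  overridable.
* Listwise deletion per analysis: animals missing the genotype, the phenotype,
  the reliability or the pedigree are dropped, with counts logged.

## Genetic-effect decomposition

From class LSMs: `a = (hom1 − hom2)/2`, `d = het − (hom1 + hom2)/2`,
`α = a + d (p − q)`.

**Orientation convention.** `hom1` is the *alphabetically first* homozygote
genotype (AA before GG, CC before TT), and `(p − q)` is
`f(major) − f(minor)`. Published effect tables for this panel are only
internally consistent under this orientation; orienting by the first-listed
allele of the substitution label (e.g. T of "T>C") contradicts the printed
signs at two loci. `d` is orientation-free. Standard errors treat allele
frequencies as known constants, so all three effects are fixed linear
contrasts of the class LSMs with SEs from the GLS covariance; two-sided
t-tests use `den_df` above. Three published cells are not reproducible from
the published class means under any orientation (c.-2012 MY α, c.-1621 MY α,
c.-724 FY a); they are excluded from round-trip checks and left as a
documented discrepancy.

## Hardy-Weinberg and frequencies

Chi-square on the three genotype classes with expected counts from observed
allele frequencies, df = 1 (3 classes − 1 − 1 estimated frequency), no
continuity correction. Monomorphic markers return (χ² = 0, p = 1) with a
warning. Missing calls are excluded marker-wise, so per-marker `n` varies —
matching how incomplete call rates behave in real panels. Frequencies are
computed at full precision; 2-decimal rounding is a report concern.

## Haplotypes, LD and blocks

* **EM** over windows of 2–8 markers (the haplotype space is exponential in
  window size), multinomial likelihood under Hardy-Weinberg pairing of
  haplotypes. Deterministic initialisation at the product of allele
  frequencies; `tol = 1e-8` on the log-likelihood, `max_iter = 1000`;
  optional seeded Dirichlet restarts (off by default). The log-likelihood is
  asserted non-decreasing on every run. Phase-unambiguous data short-circuits
  to direct gamete counting (the EM fixed point). Individuals with any
  missing call in a window are excluded from that window's EM and receive no
  diplotype.
* **LD**: `D = f(h11) − p1 p2`, `D' = |D|/Dmax`, `r² = D²/(p1 q1 p2 q2)`.
* **Blocks**: confidence-interval criterion on D'. Per pair, allele
  frequencies are fixed at sample values and the two-locus genotype
  likelihood is profiled over |D'| on a 0.001 grid; the normalised likelihood
  mass gives a two-sided 90% interval. "Strong LD" = lower ≥ 0.70 and
  upper ≥ 0.98; "strong recombination" = upper < 0.90; a block is a maximal
  run whose bounding pair is strong and in which ≥ 95% of informative pairs
  (strong ∪ recombination) are strong. These are the standard defaults of the
  CI block method; numerical agreement with any particular GUI implementation
  is not claimed.
* **Pooling**: haplotypes under 5% collapse into one POOLED class (the class
  is an ordinary factor level downstream).
* **Diplotypes**: most probable compatible pair by `f(h1) f(h2)` (×2 for
  heterozygous pairs), posterior = that term over the sum across compatible
  pairs; ties break lexicographically on the label pair; individuals
  incompatible with all positive-frequency haplotypes fall back to a uniform
  prior over compatible pairs and are flagged.

## Synthetic daughter-design generator

Defaults encode the reference design: 506 daughters from 8 sire families
(near-equal allocation; the true per-family counts are unpublished), unique
founder dams, optional grandsire layer for 3-generation pedigrees. Founder
haplotypes are drawn i.i.d. from two block frequency tables — block 1
(markers 1–4): CACT 0.348, TATT 0.319, TGTG 0.257 and the published 7.6%
rare remainder split 0.040/0.024/0.012 across TACT/TATG/CATT (this split
reproduces all published single-marker allele frequencies exactly, which is
why it is the default; it is configurable); block 2 (markers 5–6): GA 0.638,
AG 0.190, GG 0.172. Offspring receive one gamete per parent with
recombination between blocks only (default fraction 0.5 = independence, no
recombination within blocks).

Phenotypes follow the model the fitter assumes:
`y = μ + g(class) + u + ε`, `u ~ N(0, A σ²_a)` via a matrix square root of
`A`, `ε ~ N(0, σ²_e/rel)`, `rel ~ U(0.3, 0.9)` shared across traits. Class
values are `(+a, d, −a)` for (alphabetically first homozygote, heterozygote,
other homozygote), so the generating `(a, d)` are exactly what the
decomposition should recover. Default effects are the published c.-724
estimates per trait; default grand means and variance scales are
field-realistic EBV spreads (MY 500, FY 18, FP 0.15, PY 15, PP 0.05 SD units,
split 50/50 between σ²_a and σ²_e so λ = 1). Missing calls are masked at 1%
(published per-marker counts of ~496/506 imply ~98% call rates). One master
seed; per-stage substreams via fixed spawn keys; fixed seed ⇒ bit-identical
output.

**What the generator does not emulate**: selection, assortative mating,
overlapping generations, genetic correlations between traits (polygenic
values are drawn independently per trait), per-trait reliabilities, genotype
× environment, and any EBV-evaluation artefacts (EBVs are simulated directly
as noisy breeding values). Passing tests therefore demonstrate that the
estimators are correct *under the model's own assumptions* and calibrated
under this family structure — not that the model is robust to violations
real DHI data might show.

**A consequence worth knowing**: with only 8 sire families, realized allele
frequencies drift far beyond binomial error (half the gametes descend from 16
founder chromosomes), and the REML variance-ratio estimator is strongly
right-skewed (few effective between-family degrees of freedom). Tests
therefore check frequency *unbiasedness across replicates* and ratio recovery
in the mean at a 50% relative-error tolerance, rather than naive
single-replicate binomial bands.

## Problem sizes used in the checks

Oracle and calibration checks run at sizes chosen to keep the suite
desk-scale while leaving sampling error well below the tolerances tested:
gene-dropping validation of `A` at 100,000 drops on ≤25-animal pedigrees;
type-I error of the F-test and additive-effect t-test at 1,000 null
replicates of n = 200; block-structure recovery over 50 replicates of n =
500 unrelated individuals; effect and variance-ratio recovery over 30
replicates at the full 506-daughter design; EM consistency at n ∈ {100, 500,
2000}.

## Known limitations

* Single-trait analyses only; no genomic relationship matrix; no Satterthwaite
  or Kenward-Roger degrees of freedom.
* The D'-CI block finder follows the published criterion and default
  thresholds but is not a byte-level reimplementation of any specific tool.
* α's standard error ignores the sampling variance of allele frequencies
  (plug-in convention).
* The exact-test alternative for HWE (preferable at very rare alleles) is out
  of scope; the chi-square with df = 1 is what is implemented.
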