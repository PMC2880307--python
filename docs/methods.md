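# Methods

## Study design and model

The package targets the balanced inbred-line panel design: `n_lines`
near-homozygous lines, both sexes, `n_reps` replicate vials per line x sex
cell, one observation per vial (a group measurement; `flies_per_vial` is
metadata only, matching the within-vial-error reading of the residual term).
The phenotype model is the mixed two-way ANOVA

```
Y_ijk = mu + L_i + S_j + (LS)_ij + E_ijk
```

with Line random, Sex fixed (a single additive offset, split symmetrically
around the grand mean), the interaction random, and all random effects
Gaussian. On a balanced design the variance components follow from expected
mean squares by method of moments:

```
sigma2_E  = MS_E
sigma2_LS = (MS_LS - MS_E) / n_reps
sigma2_L  = (MS_L - MS_LS) / (2 n_reps)
```

Negative solutions are truncated at zero and flagged — the standard
convention for moment estimators. F tests use the mixed-model denominators
(Line and Sex over MS_LS, interaction over MS_E). Unbalanced tables are
rejected with an explicit error rather than approximated; REML is the
appropriate tool for unbalanced data and is deliberately out of scope.

## Derived statistics and conventions

- **Broad-sense heritability** `H2 = (sigma2_L + sigma2_LS) / (sigma2_L +
  sigma2_LS + sigma2_E)`. A zero total returns 0 with a degenerate flag.
- **Cross-sex genetic correlation** `r_MF = cov_fm / (sigma_f sigma_m)`:
  the numerator is the sample covariance of female and male line means; the
  denominators are among-line components from per-sex one-way ANOVAs. These
  two pieces are estimated differently, so finite samples can push |r_MF|
  past 1; such values are reported as computed with a `clamped` flag, and
  SE/p are evaluated at the clipped value.
- **Between-trait genetic correlation** `r_GT = cov_12 / (sigma_1 sigma_2)`
  with the same structure, per scope (pooled line means with two-way ANOVA
  sigmas; per-sex line means with one-way sigmas).
- **SE and p for both correlations** use the Pearson line-mean convention
  `SE = sqrt((1 - r^2)/(n - 2))` and a t test on n - 2 df. This convention
  reproduces printed values such as SE = 0.15 for r = -0.38 at n = 40. Its p
  is exact only insofar as line means estimate genetic values precisely
  (small sigma2_E/n_reps and sigma2_LS relative to sigma2_L); the
  calibration test simulates in that regime.
- **CV_G** uses `sigma_G^2 = sigma2_L + sigma2_LS`, consistent with the H2
  numerator. The line-component-only convention is available by zeroing the
  interaction field before the call; the choice between the two is genuinely
  open and this one keeps CV_G^2/CV-total coherent with H2.
- **Holm (sequential Bonferroni)** is implemented directly from its
  step-down definition (reject p_(i) while p_(i) <= alpha/(m - i + 1)) so
  boundary behaviour matches the documented contract bit-for-bit.
- **Chance expectation** of a screen is `floor(n_tests * alpha)` (with a
  1e-9 guard against binary-float droop). The floor, not half-up rounding,
  reproduces both 3,136 x 0.01 -> 31 and 10,096 x 0.01 -> 100.
- **Mutant-validation ANCOVA** fits `trait ~ genotype + sex + genotype:sex +
  covariate` (sex terms dropped when stratified) by OLS and reports the
  type-II genotype F test plus covariate-adjusted least-square means.

## Association screens

SFP markers are line-level binary genotypes, so replicate vials are
pseudo-replicates with respect to genotype; the analysis unit is the line x
sex trait mean (two rows per line). Pooled models are `Y = mu + M + S + M*S`
(SFP) and `Y = mu + S + T + S*T` (transcript); stratified screens drop the
sex terms. The reported p is the type-II F for the feature term (its sum of
squares over the sex-only model, tested against the full-model residual);
the sex-interaction p is reported alongside. Markers monomorphic after
missing-data removal, or with fewer than two lines in a class, are skipped
with a reason. No multiple-testing correction is applied inside a screen:
significance is uncorrected P < alpha (default 0.01) and the yield is
compared to `floor(n * alpha)`, with Holm available downstream.

**Known limitation.** Treating the two sex rows of a line as independent
observations is exact under the global null *without* genetic variance, and
the calibration tests simulate that case (measured rejection ~0.01 at
alpha = 0.01). When the trait has substantial among-line variance the rows
share the line effect, the residual is under-counted, and the screens are
anticonservative (~0.03 at alpha = 0.01 with components (2, 1, 1)). A mixed
model would restore calibration at the cost of the simple fixed-effects
contract; the chance-expectation comparison is the screen's intended
safeguard against over-reading the yield.

## Co-expression modules

Transcripts entering a trait's network are first residualized on the trait
(plus sex and sex x trait when per-sex layers are present) so modules are
not mere echoes of the trait association; residuals are exactly orthogonal
to the design columns. Pairwise Pearson correlations across lines are mapped
to the Euclidean-like distance `d = sqrt(2 (1 - |r|))` — the Euclidean
distance between standardized vectors up to sign; the absolute value matches
the |r| edge convention, so strong negative co-regulation also counts as
proximity. The affinity matrix `A = exp(-d^2 / (2 sigma^2))` is scanned over
30 log-spaced bandwidths spanning [0.1, 10] x the median off-diagonal
distance; each affinity graph is clustered by greedy
(Clauset-Newman-Moore) weighted-modularity maximization, and the partition
with the largest Q wins. Ties and labels are broken deterministically
(modules ordered by size, then lowest member position), so the pipeline is
reproducible and permutation-equivariant; `seed` is accepted for interface
stability but the optimizer itself is deterministic. If no bandwidth yields
Q > 0 the transcripts form a single module flagged `no_structure`.

Degree is the average |r| with module-mates (signed available by flag),
module average degree the mean over members, hubs the top-k by degree;
singleton modules have undefined degree. Edge lists contain every unordered
pair with |r| >= threshold (default 0.7). Constant transcripts are excluded
before clustering and reported.

## Pleiotropy and enrichment

Cross-trait module overlap uses the one-sided Fisher exact test (upper
hypergeometric tail, P(X >= k)), matching the "exceeds chance" question; the
universe defaults to the union of transcripts entering any trait's module
analysis and is configurable. All cross-trait module pairs are tested; raw p
is the significance call (default alpha 0.05) with BH q reported alongside.
EASE enrichment is the conservative DAVID variant: the upper tail after
removing one hit from the list-in-category cell (`k -> max(k - 1, 0)`), so
single-gene categories can never be significant; BH q is computed across
reported categories and zero-hit categories are omitted.

## Synthetic data: what it emulates and what it does not

The generator reproduces the design's *statistical* skeleton: Gaussian
line, interaction and vial effects with configurable variances; a fixed
additive sex offset; binary markers with minor-class frequencies in a
configurable range and optional (possibly sex-specific) causal shifts
injected into the phenotype; and planted co-expression modules driven by one
latent Gaussian factor per module, with member loading sqrt(within_r) so the
expected within-module correlation equals `within_r` exactly and a global
shared factor supplies any background correlation. Defaults follow the
emulated study: 40 lines, 10 vials per cell, both sexes.

It does **not** emulate microarray probe-level noise, expression
heteroskedasticity, linkage between markers, population structure, or
non-Gaussian trait distributions; passing recovery tests therefore
demonstrates correctness of the estimators under their own model, not
robustness to those features of real data.

## Numerical choices and problem sizes

- Balanced-design sums of squares are computed in closed form from cell,
  margin and grand means; screens use `numpy.linalg.lstsq` per feature with
  a scale-aware zero-SSE floor (1e-12 x max(1, y.y)) so constant inputs are
  flagged undefined rather than producing noise F ratios.
- Discrete tails come from `scipy.stats.hypergeom`; they match exact integer
  enumeration to 1e-12 for every margin with universe <= 60 (tested
  exhaustively).
- Simulation studies size: 500 panels for variance-component and
  heritability recovery (Monte-Carlo SE of each component mean ~0.02, far
  inside the 5%-of-sigma_total bound); null screen calibration over 50
  independent panels x 200 features — panels are independent because
  feature tests sharing one phenotype vector are conditionally correlated,
  which would give a single panel's rejection fraction super-binomial
  spread; 20 seeds for planted-module recovery. Per-replicate seeds are
  drawn from a single master generator, the numpy-recommended practice.
- `run-all` writes every table with `%.17g` floats; identical config + seed
  reproduces all tables byte-identically (the manifest's wall-clock stamps
  are the only non-reproducible output).

## Known limitations

- No REML: unbalanced designs are rejected, not approximated.
- Pooled screens are anticonservative under strong heritable background
  (see above).
- r_MF / r_GT can exceed |1|; the SE/p convention treats them as Pearson
  correlations of line means, which is approximate whenever line means are
  noisy estimates of genetic values.
- Modularity maximization is greedy; it carries the usual resolution limit
  for very small modules embedded in large graphs, mitigated but not
  removed by the bandwidth scan.
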