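# Methods

## Model

The analysis model is a single-trait animal model

y = Xβ + Wu + Sp + e,

with β fixed effects (intercept, coded categorical effects such as
contemporary group, optional covariates), u additive genetic values for
*all* pedigree animals with Var(u) = Hσ_u², an optional i.i.d. extra random
effect p (by default the permanent environment of the dam, shared by
littermates) with Var(p) = Iσ_pe², and Var(e) = Iσ_e². Variance components
are supplied by the user and treated as known; no REML estimation is
performed. All λ-ratios follow from them.

H combines pedigree and genomic information through its inverse,

H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A₂₂⁻¹],

which is equivalent to projecting the genomic relationships of the
genotyped set onto their ungenotyped relatives via the pedigree (the
package's tests verify the dense partitioned form of H against inv(H⁻¹) to
1e−6).

### Pedigree side

A is built by the tabular method (dense; intended scale ≤ a few thousand
animals). Inbreeding coefficients use the Meuwissen–Luo ancestor traversal,
which equals diag(A) − 1 but needs no matrix. A⁻¹ uses Henderson's rules
with inbreeding: each animal contributes 1/d_i with
d_i = ½ − ¼(F_s + F_d), replaced by ¾ − ¼F of the known parent or 1 when
parents are unknown. Unknown parents are treated as unrelated non-inbred
founders; genetic groups and metafounders are out of scope. A₂₂⁻¹ is a
dense Cholesky inverse of the A₂₂ slice.

### Genomic side

Z holds gene contents centered at per-marker allele frequencies (observed
frequencies by default; missing genotypes become 0 after centering, i.e.
mean imputation), and G_raw = ZZ′/2Σp_iq_i. With observed frequencies the
columns of Z sum to zero, so G_raw is always singular; compatibility and
invertibility come from blending,

G = (1−α)(a + b·G_raw) + α·A₂₂,   α ∈ [0, 0.05] (default 0.05),

where (a, b) solve the 2×2 system equating the mean diagonal and mean
off-diagonal of a + b·G_raw with those of A₂₂. "Equate average inbreeding
and average relationships" is operationalized as exactly these two moment
equations (two equations, two unknowns); with a single genotyped animal the
off-diagonal equation disappears and the fallback is a = 0, b = diagonal
ratio. The fitted constants and the realized moment match are logged in the
run report so blending is auditable. When known base (founder) frequencies
are used instead — as in the equivalence studies — G_raw is generically
full rank and can be used unblended (α = 0, a = 0, b = 1).

Marker QC drops monomorphic markers and those under a minor-allele
frequency (default 0.01) or call-rate (default 0.9) threshold, with a
per-marker reason report. The reference allele is whatever the input file
counts; no strand checking or imputation beyond mean fill is attempted.

## From breeding values to marker tests

The mixed model equations are assembled with σ_e⁻² included, so the inverse
of the coefficient matrix is directly the prediction-error covariance C.
They are solved by one dense Cholesky factorization; the genotyped block
C^{u₂u₂} = Var(u₂ − û₂) is obtained by solving against the genotyped
columns of the identity (equivalent to slicing the full inverse — the same
contract large-scale software meets with a supernodal selected inverse,
which is deliberately not reproduced here). Fixed-effect identifiability
uses a drop-first (treatment) coding; a sum-to-zero coding is available,
and the tests assert that p-values are invariant to the choice at 1e−10.

With k = (1−α)·b/2Σp_iq_i,

â = k·Z′G⁻¹û₂,
Var(â_i) = k²·z_i′G⁻¹(Gσ_u² − C^{u₂u₂})G⁻¹z_i,

computed with one factorization of G shared across markers (G⁻¹Z once,
then a quadratic form per marker). Gσ_u² − C^{u₂u₂} = Var(û₂) is PSD in
exact arithmetic; values in (−1e−10·σ_u², 0) are clamped to 0 and the
marker flagged `no_information`, anything more negative raises an error
because it means G and C came from inconsistent runs. p-values are the
two-sided normal tail 2(1 − Φ(|z|)); the −log10 p column is computed from
the log survival function, which is algebraically identical but does not
underflow to zero until |z| ≈ 38. Markers rare in the genotyped sample
(MAF below a few percent) have Var(â) within rounding error of zero —
their z statistic is numerically meaningless, which is one more reason the
MAF filter exists.

Two derived quantities accompany each test. The variance share
2p_iq_iâ_i² (also as a percentage of σ_u²) is a point estimate with no
uncertainty statement — the p-value, not the share, is the test. The
fixed-regression conversion is

b̂_i = (σ_a²/Var(â_i))·â_i,  Var(b̂_i) = (σ_a²)²/Var(â_i),

where σ_a² = (1−α)·b·σ_u²/2Σp_iq_i is the prior variance of one marker
effect under the model. The conversion constant matters: using the
aggregate σ_u² here scales b̂ by 2Σp_iq_i and no longer reproduces the
single-marker GLS estimates, while the z statistic is invariant either
way. The package uses σ_a², verified against the GLS scan to 1e−6.

### The EMMAX cross-check

`emmax_scan` fits, for each marker, y = Xβ + (Wz_i)b_i + ε by GLS with
Var(y) = WKW′σ_u² + SS′σ_pe² + Iσ_e², using one Cholesky of the variance
matrix and a Schur-complement solve per marker. When every phenotyped
animal is genotyped and K is the same G used by the single-step run, the
two engines' p-values agree to solver precision for *any* invertible G
(blended or not — the blending constants cancel from the z statistic); the
test suite asserts max |Δp| < 1e−8 and observes ≈ 1e−14. With ungenotyped
phenotyped animals the scan cannot form its marker covariates, so
`emmax-check` rejects that case rather than approximate it.

## Synthetic data generator

The generator emulates the study design the method targets: discrete
generations of random mating (founders split into equal sexes by default;
every female mated to a uniformly drawn male; fixed offspring per mating,
so pedigree size is exact), phenotypes on all non-founders in randomly
assigned contemporary groups, dam permanent-environment effects, and
genotyping of a configurable subset chosen sires-first (sires ranked by
progeny count), so that the typical genotyped animal is an influential
sire whose own information arrives through phenotyped offspring.
Defaults: 250 founders, 3 generations (1000 animals), 1000 markers on 29
autosomes (cattle karyotype), founder frequencies ~ U(0.05, 0.95), 30 %
genotyped, 20 contemporary groups with effect SD 1, and variance components
σ_u² = 0.48, σ_pe² = 0.10, σ_e² = 0.42 (phenotypic variance 1, heritability
0.48, maternal share 0.10).

Genotypes segregate by gene dropping: founders are Hardy–Weinberg at their
base frequencies, offspring inherit one allele per parent per linkage
block. Markers are unlinked by default; with `ld_block_size > 1` the
markers of a block share one uniform draw per founder haplotype (comonotone
alleles), planting strong within-block LD that block-wise inheritance then
preserves — inheritance alone cannot create LD from equilibrium founders.
The polygenic value is sampled recursively through the pedigree,
u_i = ½(u_s + u_d) + m_i with Var(m_i) = d_i·σ²_poly using the same d_i as
A⁻¹, so the simulated covariance is exactly A·σ²_poly including inbreeding.
Planted QTL act through (base-frequency-centered) gene contents of chosen
markers, and σ²_poly is reduced so the total additive variance equals
σ_u². All outputs are pure functions of (config, seed).

What this generator does *not* emulate — realistic LD decay, selection,
mutation, genotyping error, non-random mating — bounds what passing tests
show: they validate the algebra and the statistical calibration of the
method under its own assumptions, not its behavior on any particular real
population.

Because the polygenic truth is drawn from A while the model works with H
(which embeds the *realized* marker relationships), the null test is very
slightly conservative in marker-aligned directions; empirically the pooled
type-I error at nominal 0.05 is ≈ 0.049 and the mean genomic-control λ over
replicates is ≈ 1.00 at the default design. Per-replicate λ̂, being a
median over ~1000 correlated statistics, has sampling SD ≈ 0.08–0.11 —
individual replicates commonly land outside ±0.1 of 1 for estimator-noise
reasons alone, which is why the bundled unit test pools p-values across
replicates before computing λ.

## Reference studies and problem sizes

`ssgwas.studies` fixes three designs, chosen to run in seconds-to-minutes
on one CPU while keeping the statistical questions meaningful:

* equivalence: ~304 fully genotyped animals × 800 markers, MAF ≥ 0.05
  panel at base frequencies, unblended G;
* null calibration: 25 no-QTL replicates of the default 1000-animal /
  300-genotyped / 1000-marker design, pooled type-I error and per-replicate
  λ;
* power: 50 replicates of a ~504-animal fully genotyped design with one
  QTL sized to exactly 5 % of the additive genetic variance at its realized
  base frequency (the no-QTL generator run with the same seed exposes that
  frequency first), scored by whether the QTL has the smallest p-value on
  its 29-chromosome panel's own chromosome. At this sample size the QTL's
  expected noncentrality is ≈ 2.4–2.9, so it ranks first on its chromosome
  in roughly half the replicates — a property of the design's information
  content, not of the estimator (the realized z-statistics match the
  oracle GLS noncentrality).

## Numerical and design choices

* Dense Cholesky everywhere (scipy `cho_factor`), coefficient matrices a
  few thousand equations at most; sparse storage only for A⁻¹, H⁻¹ and
  incidence matrices.
* Blended G is validated by an actual Cholesky, not a determinant
  heuristic; failure advises raising α.
* Single trait only; no iterative reweighting of markers; no window
  aggregation of variance shares. Bonferroni is the primary threshold; a
  Benjamini–Hochberg column (`pvalue_bh`) is included as a clearly separate
  extra.
* TSV output fixed to 6 significant digits for byte-reproducible runs; a
  JSON sidecar keeps full precision.
* CLI exit codes: 0 ok, 2 input error, 3 numerical failure.
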