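# ssgwas

Frequentist p-values for genome-wide association in populations where only
part of the pedigree is genotyped.

In livestock genetics, most phenotyped animals are not genotyped: phenotypes
sit on daughters and contemporaries, genotypes on influential sires.
Single-step GBLUP (SSGBLUP) handles this by combining the pedigree
relationship matrix **A** and the genomic relationship matrix **G** into one
matrix **H**, and predicting breeding values for every animal jointly.
`ssgwas` turns those predictions into a proper single-marker association
test: SNP effects and their sampling variances are *back-solved* from the
breeding values of the genotyped animals, giving a z-statistic and p-value
per marker from a single mixed-model solve — no de-regression, no
per-marker refitting.

## The statistic

With centered gene contents `Z`, `G = ZZ′/2Σp_iq_i` (blended with `A₂₂` for
compatibility and invertibility), and the mixed model equations of

```
y = Xβ + Wu + Sp + e,   Var(u) = Hσ_u²,   Var(p) = Iσ_pe²,   Var(e) = Iσ_e²
```

solved once, with `C^{u₂u₂}` the genotyped block of the inverse coefficient
matrix (the prediction-error covariance of `û₂`), and k = (1−α)b/2Σp_iq_i
the blending scale:

```
â        = k · Z′ G⁻¹ û₂
Var(â_i) = k² · z_i′ G⁻¹ (Gσ_u² − C^{u₂u₂}) G⁻¹ z_i
pval_i   = 2(1 − Φ(|â_i / sd(â_i)|))
```

When every phenotyped animal is genotyped, `â_i/sd(â_i)` is mathematically
identical to the single-marker mixed-model (EMMAX) fixed-regression
statistic; the package ships that scan (`ssgwas.emmax_scan`) as an
independent cross-check, and `ssgwas emmax-check` verifies the agreement on
any fully genotyped dataset (typically max |Δp| ≈ 1e−14). Per-marker
variance shares `2p_iq_iâ_i²` and the fixed-regression conversion
`b̂_i = (σ_a²/Var(â_i))·â_i` are also reported.

## Worked example

Simulate a cattle-like population — 1000 animals over three generations,
300 genotyped sires-first, 1000 SNPs on 29 autosomes, one QTL planted at
marker M401 — then run the full pipeline:

```bash
ssgwas simulate --config sim.cfg --out data/
ssgwas run --config run.cfg --out out/ --plots
```

with `run.cfg`:

```
pedigree   = data/pedigree.csv
genotypes  = data/genotypes.txt
phenotypes = data/phenotypes.csv
map_file   = data/map.tsv
pe_col     = dam
sigma_u2 = 0.48
sigma_e2 = 0.42
sigma_pe2 = 0.10
alpha    = 0.05
```

The run prints:

```
tested 1000 markers on 300 genotyped of 1000 animals; lambda_gc = 1.059, Bonferroni -log10 threshold = 4.30
results written to out/results.tsv
```

`lambda_gc` near 1 says the relationship matrices absorbed the family
structure (no inflation of the test statistics); the Bonferroni line is
−log10(0.05/1000). The three smallest p-values in `results.tsv`:

```
marker_id  chrom  pos     freq    a_hat     sd_a       z   pvalue  neglog10p  var_explained_pct
     M152      5   14 0.065000 0.020898 0.006006 3.47976 0.000502    3.29942           0.011060
     M959     28   27 0.856667 0.029687 0.008567 3.46538 0.000529    3.27615           0.045091
     M401     12   21 0.631667 0.036945 0.011853 3.11703 0.001827    2.73830           0.132318
```

The planted QTL (M401) has the largest effect and by far the largest
variance share (0.13 % of σ_u²), but ranks third on the p-value scale and
below the genome-wide threshold — with only 300 genotyped animals this
amount of information is expected, and it illustrates why effect size,
variance explained and statistical significance are three different
rankings. `out/` also contains a JSON run report (blending constants a, b,
marker QC counts, λ), a full-precision JSON sidecar, and Manhattan/QQ plots
with the Bonferroni line when `--plots` is given.

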