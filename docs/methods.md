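# Methods

This note documents the statistical models implemented in `tempopgen`, the
choices made where a design was genuinely open, and what the synthetic-data
verification does and does not establish.

## Genotype-likelihood data model

All analyses consume triplets GL(g) = P(reads | g), g ∈ {0, 1, 2} minor-allele
copies, stored with each triplet scaled to a maximum of 1 (the common BEAGLE
text convention). A flat triplet (1, 1, 1) encodes a zero-read observation and
is treated as missing; an individual is "informative" at a site when its
triplet is not flat. Read-level filters (base/mapping quality, duplicates,
proper pairs) act upstream of this representation and are out of scope: the
package starts where a GL file starts.

### Allele frequency EM

The per-site minor-allele frequency is the maximiser of
ℓ(f) = Σᵢ log Σ_g GLᵢ(g)·HWE_g(f) with HWE(f) = ((1−f)², 2f(1−f), f²), found
by the standard EM f ← (2N)⁻¹ Σᵢ E[gᵢ | GLᵢ, f] over informative individuals.
Tolerance 1e-6 on |Δf|, at most 200 iterations. Two numerical refinements:
the scalar estimator restarts from f₀ ∈ {0.1, 0.5, 0.9} and keeps the
best-likelihood fit, because ℓ(f) can be multimodal for arbitrary triplets;
and the boundary values f ∈ {0, 1} are offered as explicit candidates because
EM approaches a boundary maximum only sublinearly. The vectorised
whole-matrix EM used for screening and dosage priors keeps a single start:
data generated by a genotype model do not exhibit the adversarial
multimodality, and a rare suboptimal mode there affects only a screening
threshold.

### Site filters

Sites pass, in a fixed order: chromosome exclusion (sex chromosomes are
removed before analysis), a minimum count of informative individuals, a
folded minor-allele-frequency floor (min(f̂, 1−f̂) ≥ min_maf; default 0.02),
a polymorphism likelihood-ratio test (2[ℓ(f̂) − max(ℓ(0), ℓ(1))] against
χ²(1); site kept when p < 2e-6), and a paralog screen that fits genotype
frequencies (π₀, π₁, π₂) as an unconstrained three-category mixture and
drops sites with π̂₁ > 0.5 (collapsed repeats show up as heterozygote
excess). The source tools apply these jointly; the fixed order here makes
per-filter drop counts reproducible. A configuration with vacuous thresholds
(min_maf = 0, snp_pval = 1, max_het_freq = 1, min_individuals = 0) passes
every site.

### Dosages, PCA, LD

Posterior dosages use the site's HWE prior at f̂: P(g | GL, f̂) ∝ GL(g)·HWE_g(f̂),
E[g] = P(1) + 2P(2), Var(g) = E[g²] − E[g]². A flat triplet yields the
prior-only posterior (E[g] = 2f̂). The deposited pipelines this package
mirrors obtained genotype probabilities from LD-aware imputation; since the
simulator generates unlinked sites, the per-site HWE posterior is the
appropriate (and simpler) substitute, and the two coincide when sites are
independent. PCA standardises E[g] by 2f̂ and √(2f̂(1−f̂)) per site and
eigendecomposes the individual covariance; score signs are fixed by making
each vector's first nonzero entry positive. LD r² is the squared Pearson
correlation of expected dosages; thinning scans positions in order and drops
any site with r² > 0.05 against a previously kept site within 500 kb, ties
resolved by keeping the lower position.

## Association: latent-genotype score test

For response y, covariates C (intercept, 10 PC axes recomputed on the
sex-stratum from LD-thinned sites, a library-batch indicator, and tarsus
length when the response is bill or wing):

1. fit the null OLS of y on C; residuals e, σ̂² = eᵀe/(n − rank C);
2. project the dosage: g\* = E[g] − C(CᵀC)⁻¹Cᵀ E[g];
3. U = g\*ᵀe/σ̂², I = (g\*ᵀg\* + Σᵢ Var(gᵢ))/σ̂², T = U²/I ~ χ²(1).

The Var(g) term inflates the information for uncertain genotypes, so the test
is exact (equal to the classical score test) for certain genotypes and
conservative otherwise — measured type-I error at 4X is ≈ 0.027 at α = 0.05,
versus 0.048 with certain genotypes. Calibration checks therefore run in the
certain-genotype regime, where the χ²(1) reference must hold exactly.
Morphological responses use "contemporary" samples only (year ≥ 2005);
year and climate responses use all years. Sites with folded f̂ < 0.1 are not
tested; candidates are sites with p < 1e-5.

## Diversity

The SAF vector at a site over n individuals is the coefficient vector of
Πᵢ [GLᵢ(0) + 2GLᵢ(1)x + GLᵢ(2)x²], coefficient j divided by C(2n, j) —
P(data | j copies among 2n chromosomes) up to a site constant. Convolutions
are renormalised per individual so n > 50 cannot underflow. Missing
individuals contribute (1 + x)², i.e. nothing after the binomial division,
so n_chrom is fixed at 2× the group size. The SFS is the EM maximiser of
Σ_s log Σⱼ φⱼ·SAF_sj on the simplex (folding sums bins j and 2n−j before the
EM); θ_W = S/a with a = Σ 1/i, and π uses the pairwise weight
j(2n−j)/C(2n, 2), which is symmetric under folding. Windows are 0-based
half-open 10-kb tiles; a year enters only with ≥ 5 sampled individuals.
Windows with fewer than 50 informative sites are flagged `low_data` and
excluded from trend fits — the EM is unstable on tiny windows (this rule is
a package choice; upstream descriptions are silent).

**Individual heterozygosity** fits the *unfolded* three-bin single-individual
SFS and reports the heterozygous mass. Folding is deliberately not used here:
merging the two homozygote bins lets a heterozygous site whose few reads all
happen to show one allele be explained as the opposite homozygote, and the
folded two-bin maximum likelihood is then inconsistent (≈ 0.4× truth at 4X in
our measurements, not improving with more sites). The unfolded mixture
contains the true genotype proportions and recovers them.

Two identifiability facts shape the verification designs. First, the ML SFS
at 4X is "spiky": adjacent high-frequency bins are nearly confounded, so with
a dense spectrum (θ ~ 0.2) the converged estimate plateaus at total-variation
≈ 0.14 from truth regardless of iterations. At realistic vertebrate
polymorphism densities (θ ≈ 0.05 and below) recovery is within TV 0.05, and
that is the regime the recovery study simulates (2,000 sites, 10 diploids,
4X). Second, folding before versus after the EM agrees closely only once the
data identify the spectrum: measured TV between the two is 0.11 at 6X, 0.017
at 10X, 0.004 at 15X; the consistency test runs at 12X.

## Marker effects and the selection test

Ridge BLUP solves y = Xb + Zu + e, u ~ N(0, σ²_u I), with Z the raw (0–2)
expected dosages at candidate SNPs and X an intercept by default (whether the
original analyses put PCs inside the ridge model is unstated; a covariate
argument is provided). REML profiles the restricted likelihood on
λ = σ²_e/σ²_u through one eigendecomposition of U₂ᵀZZᵀU₂ (U₂ an orthonormal
basis orthogonal to X), scans λ on a 121-point log grid over [1e-6, 1e6] and
refines by bounded minimisation; û = Zᵀ(ZZᵀ + λI)⁻¹(y − Xb̂). At a fixed,
externally supplied λ the closed form (ZᵀZ + λI)⁻¹Zᵀ(y − Xb̂) is returned
exactly. β_Trait uses contemporary samples of one sex; β_Year uses all years
of the same sex; cross-sex transfer re-estimates β for the same SNPs in the
opposite sex. The comparison statistic is Spearman's ρ with average-rank
ties; for n ≤ 9 pairs the two-sided p is the exact permutation tail over all
n! orderings, above that the t approximation. A negative ρ says the alleles
that most increase the trait fell fastest in frequency.

## Morphology and climate

Trait models are OLS fits of trait ~ year + sex + year:sex with terms dropped
sequentially under marginality (never an interaction without its mains);
model choice minimises AIC = n·log(RSS/n) + 2k, k = coefficients + 1 — the
Gaussian-likelihood constant is pinned so reported AIC values are
reproducible. Relative traits divide bill and wing by tarsus; rows with
missing or non-positive tarsus keep their absolute values. Row filters
(spring months March–May, no hatch-year birds, sex required) are declarative
and report per-rule drop counts. Period contrasts are differences of period
means with percent change relative to the earlier period.

Climate grids are summarised per point, year and season — breeding =
June–July, winter = January–February — by the 95th quantile of daily maxima,
the 5th quantile of daily minima (robust stand-ins for seasonal extremes)
and total precipitation. Quantiles use linear interpolation between order
statistics (type 7; the convention was unstated and is pinned here). Seasons
are selected by calendar month, so leap years are handled by dates, not
day-of-year indices. Per-point trends are Spearman correlations of the
yearly summary with year (exact-permutation p at small n), and the range
summary is the percentage of points with ρ > 0 among points where ρ is
defined (constant series are flagged undefined; ρ = 0 counts as not
increasing).

## Annotation

Genes are read from GFF3 `gene` records (sorted internally; malformed rows
are rejected with their line number). For each candidate SNP, every site
within 500 kb on the same chromosome with |r| ≥ 0.9 dosage correlation joins
the linked set; genes overlapping the spanned interval are reported. The
threshold is on |r|, not signed r, because the sign flips with the arbitrary
major/minor orientation; the search window mirrors the LD-thinning window
since the original tool's window is unstated. Raising the threshold can only
shrink spans.

## The synthetic-data generator

The generator emulates the downstream products of a museum-cohort
resequencing design, with defaults matching that design: sampling years
1986–2014 at 8 birds/year (232 individuals), two sexes, two library batches
split by sampling-year halves, mean depth 4 reads/site (Poisson), read error
0.01, three traits (bill, tarsus, wing; means 9.3/30/89 mm with per-trait
scales) with 8 causal loci each and heritability near 0.5, residuals
correlated 0.3 across traits, sex effects (males larger tarsus and wing,
females marginally larger bills), drift at Nₑ = 5000, and selection pushing
bill length down at 0.03 phenotypic SD per year. Causal frequencies respond
deterministically by Δp = s·β·p(1−p)/σ_G (σ_G recomputed from the current
year's frequencies), then all sites drift by binomial resampling of 2Nₑ
gametes. Individuals are drawn independently from their sampling year's
frequencies — no pedigree, no overlapping generations, matching analyses
that treat samples as unrelated. Sites are unlinked; LD-dependent tests
build correlated genotypes directly. Effect distributions: `normal`
(N(0, effect_sd), the realistic default), `fixed` (±effect_sd), and `graded`
(evenly spaced magnitudes with random signs — the equal-power design used in
the recovery studies, where every locus must be individually detectable and
the magnitudes carry a true ordering). All randomness flows from one seed
through named substreams; identical configs are bit-identical, including
gzip output (zeroed timestamps).

What passing recovery tests shows: the estimators recover the truth of this
generative model at the study's sample sizes and depth. What it does not
show: robustness to linkage, population structure, batch-depth confounding,
reference bias, or model-misspecified read errors, none of which the
generator produces.

## Verification study designs

- **Null calibration**: 10,000 permuted-null sites, 200 individuals, certain
  genotypes (see score-test section): rejection rate at α = 0.05 and KS
  uniformity of p-values.
- **SFS recovery**: 2,000 sites at 4X from a neutral spectrum with θ = 0.05
  over 10 diploids; total-variation distance to the true folded histogram.
- **Windowed diversity**: 30 windows × 400 sites at θ = 0.005 per site with
  15 diploids at 4X (invariant sites included so estimates are on the genomic
  scale); window-mean θ_W and π against the simulated θ.
- **Heterozygosity**: one individual, 50,000 sites, true het fraction 0.002,
  4X.
- **Selection recovery** (the headline inference): 30-year cohorts of
  150 birds/year, 600 sites, 8 graded bill loci (h² ≈ 0.9 so each locus
  clears the genome-wide cutoff at ~750 contemporary males), gradient
  −0.06 SD/year (frequency shifts of 0.1–0.2 without fixation), Nₑ = 20,000.
  Each replicate runs GWAS (10 PCs, library and tarsus covariates) →
  candidates at p < 1e-5 → ridge β_Bill and β_Year → Spearman comparison;
  20 replicates with selection versus 20 drift-only replicates. These sizes
  keep the full verification suite to a few minutes while leaving the
  qualitative design (three decades, low coverage, sex stratification)
  intact.

## Known limitations

- The GWAS information inflation makes low-depth p-values conservative rather
  than calibrated; power comparisons across depths should use simulations,
  not nominal α.
- Diversity on SNP-only panels measures per-SNP diversity, not genomic
  diversity: include invariant sites in the GL matrix for genomic-scale θ.
- The folded SFS at 4X is weakly identified in high-frequency bins; window
  statistics (θ_W, π) are robust to this but the spectrum shape itself is
  not.
- The exact-permutation Spearman test is discrete: with 4 candidate SNPs the
  smallest two-sided p is 1/12, so very small candidate sets cannot reach
  conventional significance regardless of effect ordering.
- `mixed.solve`-style REML assumes a single variance component; structured
  relatedness (a GRM random effect) is out of scope.
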