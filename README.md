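# tempopgen

Temporal population genomics from genotype likelihoods: did the alleles behind
a shifting trait shift too?

Museum and long-term collections let us resequence cohorts of the same
population sampled across decades. At the low coverage (~4X) such specimens
allow, genotypes cannot be called confidently, so every analysis here works
directly on genotype likelihoods (GLs): per site and individual, the three
probabilities P(reads | g) for g ∈ {0, 1, 2} copies of the minor allele.
`tempopgen` implements the full chain of analyses for asking whether a
morphological trend (for example, shrinking bills in a migratory songbird) has
a genetic basis:

- **glcore** — BEAGLE-format GL I/O, EM allele frequencies under
  Hardy–Weinberg, polymorphism likelihood-ratio screening, a
  heterozygote-excess paralog filter, posterior allelic dosages
  E[g | GL, f̂], PCA on frequency-standardised dosages, and LD thinning.
- **assoc** — sex-stratified GWAS by a latent-genotype score test. With null
  residuals e, residual variance σ̂², and covariate-projected dosage g\*:
  U = g\*ᵀe/σ̂², I = (g\*ᵀg\* + Σᵢ Var(gᵢ))/σ̂², T = U²/I ~ χ²(1). The
  posterior dosage variance inflates the information, so genotype uncertainty
  can only make the test conservative; with certain genotypes it is the
  classical score test.
- **diversity** — sample-allele-frequency (SAF) likelihoods by polynomial
  convolution, folded site-frequency-spectrum estimation by EM, Watterson's
  θ_W = S/a and nucleotide diversity π = Σⱼ j(2n−j)/C(2n,2)·η̃ⱼ in
  non-overlapping 10-kb windows per sampling year, and per-individual
  heterozygosity.
- **effects** — ridge-regression BLUP marker effects (y = Xb + Zu + e,
  u ~ N(0, σ²_u I)) with REML variance components via a spectral
  decomposition; β estimated at candidate SNPs once with the trait as
  response (β_Trait) and once with collection year (β_Year); Spearman's ρ
  between them (exact-permutation p for n ≤ 9) is the test for selection
  moving trait-associated alleles; cross-sex effect transfer.
- **phenoclim** — trait ~ year + sex + year:sex models with AIC term
  selection, relative traits (bill or wing over tarsus), period contrasts,
  seasonal climate summaries (5th/95th quantiles, precipitation totals) and
  per-grid-point Spearman trends.
- **annotate** — candidate SNP → gene linkage via local LD (|r| ≥ 0.9 within
  a window) against a GFF3 annotation.
- **simulate** — a forward simulator with known truth: polygenic traits,
  directional selection moving causal allele frequencies
  (Δp = s·β·p(1−p)/σ_G per year) plus binomial drift, low-coverage read
  sampling, and a synthetic climate grid. Every stage of the analysis is
  verified by parameter recovery against this generator.

## Worked example

The bundled demo simulates a 29-year cohort (1986–2014, 40 birds/year) with
five graded-effect bill-length loci under selection for smaller bills
(s = −0.08 SD/year), writes BEAGLE GLs, a sample table, a synthetic gene
annotation and a climate grid, then runs the whole pipeline:

```bash
tempopgen pipeline demo --seed 42 --outdir demo_out
```

Among the outputs in `demo_out/results/`, `candidates_bill_M.tsv` holds the
male bill-length GWAS candidates:

```
chrom     pos       maf          T             p
chr1    29000  0.170436  23.834925  1.049606e-06
chr1    76000  0.185931  36.861153  1.268484e-09
chr1    89000  0.416004  27.253185  1.784808e-07
chr1   102000  0.480021  11.730745  6.147597e-04
```

and `effect_comparisons.json` the headline comparison:

```json
"bill_M": {
  "rho": -1.0,
  "p": 0.08333333333333333,
  "n": 4,
  "method": "exact-permutation"
}
```

ρ = −1 means the candidate alleles that most increase male bill length are
exactly the ones whose frequencies fell fastest over the 29 years — the
signature of directional selection on the trait (with only 4 candidates the
exact-permutation p bottoms out at 2/24 ≈ 0.083; the full-scale verification
below uses larger cohorts). `climate_summary.json` reports
`"fraction_increasing_pct": 91.66...` for a synthetic grid built with 90%
truly-warming points, and `morphology_models.json` records the AIC-selected
trait models, e.g. `bill ~ year + C(sex) + year:C(sex)` with a negative year
coefficient.

Every stage is also a standalone command (`tempopgen filter`, `gwas`,
`diversity`, `effects-compare`, `annotate`, `morpho`, `climate`,
`pipeline run --config config.yaml`) and a plain library call.

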