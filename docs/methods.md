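# Methods

`exwaskit` re-creates, at desk scale, an imputation-powered exome-wide
association study of kidney function: a sequenced subset of a cohort
serves as a within-cohort reference panel from which exome variants are
imputed into array-only participants, and the combined cohort is then
scanned variant-by-variant and gene-by-gene for associations with five
kidney biomarkers. Because the individual-level data such studies use
are access-controlled, every analysis stage here runs on synthetic
cohorts whose statistical structure is generated by the package itself.
This note records the models, the parameters that matter, and the
choices made where the design was open.

## Synthetic cohort model

**Haplotypes.** Haplotypes are founder mosaics: each of the
H = 2·n haplotypes copies a path through `n_founders` (default 60)
founder haplotypes, switching to a uniformly random founder between
adjacent sites with probability 1 − exp(−ρ·d) for distance d bp and
`mosaic_switch_rate` ρ (default 2×10⁻⁶/bp, i.e. ~500 kb copying
segments over the default 2.5 Mb region). Sites are of two kinds:

* *Founder-polymorphic* sites segregate among the founders with derived
  founder count k drawn from P(k) ∝ 1/k^`founder_freq_shape`
  (default shape 1). These become the common variants and carry the
  linkage disequilibrium that imputation exploits.
* *Recent-mutation* sites model rare variants. Each picks one founder
  lineage; every haplotype copying that founder at the site carries the
  derived allele independently with probability
  `private_mutation_rate` (default 0.5; at least one carrier is
  forced). Rare alleles therefore sit on a shared identifiable
  haplotype background, as identity-by-descent puts them in real
  cohorts. Strictly private single-haplotype mutations would be
  unimputable by construction and would make the whole imputation arm
  of the study vacuous, which is why the generator ties carriers to a
  copying lineage instead. With 60 founders the expected rare-site
  minor allele frequency is `private_mutation_rate`/`n_founders` ≈
  0.8%, i.e. below the 1% analysis cutoff at every cohort size.

The generator logs, per site, its kind, founder-derived count, chosen
lineage, copier count and realized carrier count, so frequency-spectrum
properties are testable against the generator's own bookkeeping rather
than against the emitted matrix.

**Cohort split.** `round(ref_fraction · n)` individuals are "sequenced"
(default fraction 166,891/408,511 ≈ 0.409, the sequenced share of the
emulated study); `n_holdout` of them are withheld for imputation
validation. Array sites are sites with reference-panel MAF ≥ 0.03,
thinned to 80% density — a dense common-variant scaffold of the kind
genotyping arrays provide.

**Annotations.** Contiguous position blocks form genes. Consequences are
multinomial (35% synonymous, 45% missense, 15% HIGH-impact classes, 5%
other); a latent deleteriousness d ∈ [0,1] is drawn high for
HIGH-impact and uniform for missense variants, and every in-silico
score (CADD-, REVEL-, MetaSVM-, FathMM-XF-like, M-CAP class) is an
affine function of d plus independent noise. The latent d stays in the
table so that score–deleteriousness attenuation is testable in closed
form.

**Phenotypes.** A latent kidney-function factor
U = Σ β_v g_v + N(0,1) collects the effects of rare damaging variants
in the shared-kidney causal genes (plus a few small-effect common
variants). The eGFR analogs are linear in U on the eGFR scale
(95 + 12·U ml/min/1.73 m²) with per-trait noise (SD 0.82 in U units,
which fixes the eGFRcrea–eGFRcys correlation near 0.61); serum
creatinine and cystatin C are produced by inverting the CKD-EPI
equations, so that re-applying those equations downstream recovers
exactly the simulated eGFRs. Urea loads on −U; urate and urinary
albumin are driven by their own causal gene sets. ICD-10 codes (N18.3,
M10.0) are drawn with probabilities rising as eGFR falls or urate
rises. Ages are Uniform(40, 70), 54% female. Causal effect sizes are
|β| = 1.8·(0.4 + 0.6·d) latent-factor SDs per allele — deliberately
large: a ~600-individual cohort stands in for a ~400,000-participant
biobank, and the effect scale is chosen so that rare-variant power at
desk scale is comparable to the study's power at biobank scale. The
architecture is a free parameter of the generator, not an estimate of
any real genetic architecture.

## Imputation

Each target haplotype is imputed with a haploid Li–Stephens copying
model: hidden states are the reference haplotypes (uniform prior);
between adjacent sites the chain jumps to a uniformly random state with
probability θ(d) = 1 − exp(−`switch_scale`·d/H); typed sites emit the
observed allele with error `emission_error` (default 10⁻³). Because the
uniform-switch kernel composes exactly over distance, running the
forward–backward recursion over typed sites only and interpolating the
posterior into each untyped interval is *identical* to running the
chain over every site; the unit tests verify this against brute-force
path enumeration. Untyped-interval interpolation is evaluated with
matrix products shared across the interval, which keeps the cohort-level
cost at O(typed sites × H × targets) plus three GEMMs per interval.

Chunking follows the large-cohort recipe: cores of `chunk_size`
variants padded by `overlap` bp (defaults 30,000 and 1 Mb, matching the
procedure the module emulates; desk presets use smaller chunks),
imputed independently, trimmed by `trim` bp (= overlap/2) of padding at
interior ends, and concatenated with each site taken from the chunk
whose core owns it. One caveat found while validating: the chain's
information horizon can exceed the overlap when `switch_scale` is small
(sticky chains carry evidence far), so chunk-boundary agreement is
exact only relative to that horizon; the consistency test uses a
short-memory chain to isolate the bookkeeping.

Per-site quality is summarized two ways, both on haploid dosages d with
p̂ = mean(d): the minimac-convention rsq = mean((d−p̂)²)/(p̂(1−p̂)) and the
IMPUTE-style info = 1 − mean(d(1−d))/(p̂(1−p̂)); both are defined as 0 at
monomorphic estimates and clipped to [0,1]. Hard calls round dosages to
the nearest integer with exact .5 ties going down (toward fewer
alternate alleles). Merging imputed targets with the sequenced subset
keeps sites with missingness ≤ 0.05 and rsq > 0.3.

## Holdout validation

Withheld sequenced individuals are imputed from the panel that excludes
them and scored against their true genotypes in reference-panel
frequency bins: one bin per MAC 1–10, then MAF intervals with edges
(0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.5). Metrics: squared
Pearson correlation of dosage with genotype (zero-variance variants
excluded and counted), genotype-class concordance, and carrier
TPR/TNR/FPR/FNR with carrier = het or hom-alt. Concordance and carrier
rates are pooled (micro-averaged) within bins — genotype counts over
genotype counts — which keeps single-digit-MAC bins well defined;
per-variant macro-averaging is available as an option. With these
pooled definitions TPR + FNR = 1 and TNR + FPR = 1 identically, so no
attempt is made to reproduce published TPR/FNR pairs that are not
complementary. Array sites are excluded from evaluation. At the default
desk scale the overall median holdout r² is ≈ 0.98–0.99 and the
seed-averaged mean r² rises monotonically from ≈ 0.6 at MAC 1 to ≈ 0.97
at MAC 10 — the qualitative shape, not the magnitudes, is the design
target.

## Association analysis

Biomarkers are transformed exactly as the emulated analysis prescribes:
CKD-EPI eGFR (2009 creatinine and 2012 cystatin C coefficient sets,
race term omitted for a single-ancestry cohort; coefficients are
configurable), eGFR winsorized to [15, 200], UACR in mg/g with
below-detection albumin set to the detection limit (6.7 mg/L; urinary
creatinine converted at 113.12 g/mol), rank inverse-normal transform
Φ⁻¹((rank − 0.5)/n) with mean ranks for ties, then OLS residualization
on age and sex (genetic principal components are not simulated — the
cohort is homogeneous — but the covariate machinery is the same).
Binary traits: CKD = any N18.* code, gout = any M10.*, microalbuminuria
= UACR > 30 mg/g.

The single-variant scan is fixed-effect OLS of the residualized
phenotype on allele dosage. The whole-genome LMM used at biobank scale
exists to absorb relatedness and structure; the simulated cohort has
neither, so the fixed-effect model is exact rather than an
approximation. Dosages are projected off the covariates so the scan
reproduces full-covariate OLS coefficients (Frisch–Waugh), with
two-sided p from the t distribution at the full model's residual
degrees of freedom. Effects are reported for the minor allele. Binary
traits use per-variant logistic regression; complete separation is
flagged, the effect presented as a bound (|OR| capped at 1000) and p
taken from the likelihood-ratio test.

Variant inclusion: canonical transcript, MAC ≥ 5, MAF < 1%, info ≥ 0.5,
rsq ≥ 0.3, impact at least LOW, consequence not synonymous. The
Bonferroni threshold is α / (effective phenotypes) / (tests); with the
study's printed counts — 1,844,188 variants, 18,727 genes, 4 effective
phenotypes (five biomarkers minus one for the 0.61 eGFR correlation) —
this reproduces 6.78×10⁻⁹ and 6.67×10⁻⁷; desk-scale runs use their own
test counts in the same formula. Genomic control λ is the median
observed χ² over 0.45494. At 10⁵ tests the median-based λ estimate has
Monte-Carlo SD ≈ 0.007, so calibration checks compare the across-seed
mean of λ to the [0.99, 1.01] band rather than single draws.

## Gene-level analysis

Two masks select rare (MAF < 1%, rsq ≥ 0.3) damaging variants per gene:
`ptv_dmg` = high-confidence LoF, or missense with MetaSVM-like > 0, or
FathMM-XF-like > 0.5; `dmg_cadd` = missense-or-worse with CADD-like
> 20, or REVEL-like > 0.5, or M-CAP deleterious. The CADD clause is
read as tied to the consequence (the mask's name implies it), the REVEL
and M-CAP clauses as score-only; severity order for "missense or worse"
is missense < splice < frameshift/stop_gained, with synonymous and
other below. The burden score is the unweighted sum of minor-allele
hard calls over a gene's mask variants, missing calls mean-filled per
variant, tested with the same regression machinery as single variants.

Significant gene signals are decomposed by ordering mask variants by
single-variant p (ties broken by position, then index): add-one-in runs
the burden test on the i best variants for i = 1..n; leave-one-out
removes the i best for i = 0..n−1. The spread statistic is the *sample*
SD (n−1 denominator; the convention is recorded in the output metadata)
of −log₁₀ of the add-one-in p-vector; a gene-trait signal is
multi-variant when it is ≥ 0.5. Category 1 = multi-variant and p₁ not
itself significant (at least two variants needed); category 2 =
multi-variant with p₁ significant; category 3 = not multi-variant. A
single-variant gene has SD 0 by convention and falls in category 3.

## Prioritization

Per gene, the best p and its effect sign are collected per trait from
both sources (single-variant lead and best-mask burden). A gene is a
kidney-function gene when (i) it is significant for eGFRcrea or eGFRcys
— through either source at that source's threshold; (ii) the two eGFR
effect signs agree; (iii) the non-lead GFR estimate is nominally
associated (p < 0.05, any source); and (iv) urea and the CKD indicator
associate opposite in sign to the eGFR effects (signs only for CKD —
no p cutoff). Genes lacking urea or CKD statistics are excluded as
incomplete and logged. A creatinine-pathway-only causal gene (analogous
to a transporter affecting creatinine secretion, not filtration) fails
(iii)/(iv) because its signal does not transfer to cystatin-based eGFR,
urea, or CKD; this discrimination is exercised in the tests.

## Problem sizes and presets

The default configuration is 600 individuals, 2,500 sites over 2.5 Mb,
60 genes; a full pipeline run takes seconds and the multi-seed property
checks minutes on one CPU. Presets: `test` (200 × 2,000; the
MAC ≥ 5 ∧ MAF < 1% window is empty by arithmetic at n = 200, so this
smoke preset widens MAF to 5%), `desk` (2,000 × 8,000, 120 genes) and
`paper-shaped` (4,000 × 12,000, 150 genes, sequenced fraction 0.409).
These sizes are the package's own choices for a single-CPU desk run.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of a biobank exome
study: LD suitable for imputation, a rare-heavy frequency spectrum,
imputation quality that rises with MAC, correlated biomarkers with
shared and biomarker-specific genetics, and direction patterns
(eGFRcrea ↔ eGFRcys positive, eGFR ↔ urea negative). It does not model
population structure, relatedness, sequencing or genotyping error,
X-chromosome inheritance, multi-allelic sites, medication effects, or
realistic effect-size distributions, and its headline numbers
(significant-variant counts, λ, median r²) are properties of the
synthetic conditions, not reproductions of any published value. Passing
tests therefore certify the correctness and calibration of the
*machinery* — imputation, transforms, tests, decomposition, selection
logic — under known truth, not the biology of any real cohort.

## Numerical notes

Forward–backward vectors are renormalized at every typed site;
posterior sums are exact to 1e−9 by construction. Dosages are clipped
to [0, 2] after summing haploid posteriors. All randomness flows from
`numpy.random.default_rng` seeds; the pipeline expands one global seed
into independent per-stage substreams via `SeedSequence`, so any stage
can be re-run in isolation bit-identically. Zero-variance dosages and
burdens are skipped with warnings rather than producing NaN statistics;
rank-deficient covariate designs raise, while collinear common-variant
adjustment sets drop columns greedily with a warning.
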