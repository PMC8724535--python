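# Methods

## Scope and data model

The package models the analysis chain linking common-variant polygenic
burden for Parkinson's disease (PD) to the MDS research-criteria
probability of prodromal PD (pPD) in a population cohort of older
adults.  Its in-memory containers are a dosage `GenotypeMatrix`
(individuals × biallelic variants, values {0, 1, 2} with NaN for missing
calls), `SummaryStatRecord`s for the discovery GWAS, `MarkerProfile`s
holding each individual's risk/prodromal marker states and cognitive
z-scores, and tidy pandas frames for results.

## Genotype quality control

Filters and thresholds follow standard array-QC practice for association
cohorts:

| filter | rule |
|---|---|
| sample missingness | > 0.05 excluded |
| heterozygosity rate | beyond mean ± 6 SD excluded |
| relatedness | pi-hat > 0.125 (third-degree cut-off), greedy pruning |
| ancestry outliers | > 6 SD on any of the first k PCs |
| variant missingness | > 0.05 within any genotyping batch |
| differential missingness | chi-square across batches, p < 10⁻¹⁰ |
| Hardy–Weinberg | chi-square (1 df), p < 5·10⁻⁸ |
| strand-ambiguous variants | A/T, C/G with MAF > 0.4 removed |
| duplicate variants | same (chrom, pos, allele set): lowest missingness kept |

Heterozygosity statistics are referenced to the samples that survive the
missingness filter.  A chromosome-X sex-consistency check requires data
the pipeline does not model; it is logged as skipped rather than
silently dropped.

Kinship is the method-of-moments estimator on standardized dosages
(average cross-product over pairwise-complete variants), clamped to
[0, 1] with self-kinship defined as 1.  Greedy pruning processes flagged
pairs in deterministic id order and removes the member with higher
missingness (ties toward the lexicographically larger id).

**Ordering.**  Relatedness is pruned before PCA so that a duplicate pair
cannot form its own principal axis and be misread as an ancestry
cluster.  Samples whose kinship self-variance exceeds 1.5 — the
signature of a genotype profile drawn from shifted allele frequencies —
are exempted from kinship pruning and left to the PCA outlier step;
otherwise an ancestry outlier's distorted pairwise estimates can knock
out a random clean partner.  For a homogeneous cohort the self-variance
concentrates near 1 (SD ≈ 0.07 at 2,000 variants), so 1.5 is a
conservative margin.  After all exclusions, per-variant MAF and call
rate are recomputed on the analysis cohort (the scoring filters
reference it), and a final PCA on the clean matrix yields the ancestry
covariates MDSC1/MDSC2 (orthonormal components of the
binomially-standardized dosage matrix, mean-imputed per variant).

## PRS construction (clumping + thresholding)

Target variants are filtered at MAF > 0.05, call rate > 0.95 and
imputation quality > 0.4 (all strict; absent quality scores default to
1.0, the genotyped-variant convention).  Harmonization matches on
(chrom, pos): equal alleles keep the discovery beta, swapped alleles
negate it, strand flips are resolved by complementing, and ambiguous
pairs that would match only after a flip are dropped and counted.

Clumping is greedy on ascending p (ties by chromosome and position):
each index SNP removes remaining SNPs on the same chromosome within
±250 kb whose squared Pearson correlation of mean-imputed dosages in the
*target* cohort exceeds 0.1.  The window is interpreted as ±250 kb from
the index SNP; region exclusion (default chr6:27–33 Mb, hg19, both ends
inclusive) is applied before clumping.  Thresholding is strict (<), so
subsets are nested across the threshold ladder.  Missing dosages score
as twice the cohort effect-allele frequency (mean imputation).  Scores
are reported raw; quartiles are cut at the 25/50/75 sample percentiles
(linear interpolation), with boundary ties assigned to the lower
quartile.

## pPD probability

The calculator is a naive-Bayes update on the odds scale: an age-band
pretest probability (bands half-open [lo, hi), the last open-ended; ages
below the first band are an error), one likelihood ratio per configured
marker (LR⁺ present / LR⁻ absent / exactly 1.0 missing), total risk and
prodromal LRs as products, and posttest probability from
odds × total LR.  An identity update (total LR = 1) returns the pretest
probability bit-exactly.  Cut-offs at 30/50/80 % are inclusive (≥).
Individuals with diagnosed PD or dementia with Lewy bodies are
pre-filtered with a logged count.  Sex-specific markers (erectile
dysfunction) are missing for females and therefore contribute 1.0.

The LR values and age priors are configuration, not code: the packaged
table carries the 2019 revision of the criteria, and any run can swap in
another YAML; the table's SHA-256 is written to the run manifest.
Sensitivity operations are expressed as LR overrides: marker exclusion
forces one marker's LR to 1.0 for everyone (dividing each total LR by
exactly the factor that marker contributed), and the PRS-quartile
substitution replaces the family-history LR with 1.57 / 1.00 / 0.45 for
the top / middle / bottom quarters of the cohort PRS distribution.

## Association layer

Linear models are OLS with t-based 95 % CIs; "log-transformed" outcomes
use the natural log (slope ≈ proportional change per PRS unit), dropping
non-positive rows with a logged count.  Binary outcomes use
maximum-likelihood logistic regression (Newton iterations, gradient
tolerance 10⁻⁸, ≤100 iterations) reporting OR = exp(β) with Wald CIs;
separation or non-convergence yields a flagged result with estimates
withheld rather than a misleading fit.  Quartile contrasts keep all rows
(Q2–Q4 dummies against Q1) and additionally report Q4-vs-rest and an
ordered 1–4 trend p.  Group comparisons dispatch t-test / ANOVA or
Mann–Whitney / Kruskal–Wallis on an explicit normality flag, and
chi-square for categorical variables.

The model battery crosses every PRS threshold with: log pPD probability,
the ≥30 % and ≥50 % cut-offs, log total risk and prodromal LRs, each
prodromal marker, and each cognitive-domain z-score.  Outcomes computed
from age and/or sex are adjusted for MDSC1+MDSC2 only (adjusting for a
variable that is an input of the outcome would be circular); marker and
z-score outcomes add age and sex; a fully-adjusted variant of the
ancestry-only rows is available as an exploratory option.  P-values are
nominal; a Bonferroni column is emitted as a labelled convenience only.
All models are complete-case.

## Synthetic cohorts

The generator's defaults are the study conditions the pipeline is
validated under: n = 1,120 individuals aged 65–90 (uniform; only band
membership matters for the priors), 57.6 % female, 5,000 biallelic
variants with allele frequencies uniform on [0.05, 0.5], genotypes from
a Gaussian copula over two haplotypes with AR(1) correlation 0.35 inside
blocks of 10 variants (HWE holds exactly at each drawn frequency; blocks
are independent, giving tunable r² for clumping tests), 0.5 % genotype
missingness, and three genotyping batches.

The discovery GWAS is simulated directly at the (effect, p) level: 2.4 %
of variants (120 at the default size) carry true effects N(0, 0.05²);
every variant's estimate is truth plus noise at the standard error
1/√(2·N·p·(1−p)) of a discovery sample of N = 450,000, with two-sided
Wald p-values.  These values yield a genome-wide-significant tier of
roughly 85–95 SNPs after clumping, matching the intended structure of a
large PD meta-analysis used at the 5·10⁻⁸ threshold.

The oracle liability is the standardized weighted sum of centered causal
dosages.  Five cognitive-domain z-scores load on it negatively with
weight 0.3 (then restandardized); global cognitive deficit, dementia and
MCI are the bottom cohort quantiles of the composite z at 16.5 %, 3.5 %
and 12.8 % — so deficit probability rises with liability, and setting
the loading to zero decouples them exactly.  The deficit definition is
exposed as either a prevalence quantile (default) or a fixed z
threshold, since composite-based operationalizations vary between
neuropsychological batteries.  All other markers are independent
Bernoulli draws at prevalences plausible for a community-dwelling 65+
cohort, chosen once so that ≈5 % of individuals land at ≥30 % pPD
probability (≈2 % at ≥50 %, with a median probability near 2 %).
Erectile dysfunction is drawn for males only; every marker state is
independently set to missing at 2 %.

Injectable QC failures come with a truth log.  Two constructions deserve
note: the ancestry outlier redraws one sample's genotypes from a
strongly shifted allele-frequency profile balanced (greedily, per
variant) to keep its expected heterozygosity at the cohort mean — so it
is detectable by PCA but not a heterozygosity outlier; and the
duplicate-variant copy receives exactly 1 % extra missingness, enough to
lose the dedup tie-break but far from the 5 % missingness rule.

**What the generator does not emulate:** realistic human LD maps and
MAF spectra, imputation dosage uncertainty, population structure beyond
mean-shifted outliers, correlated marker comorbidity, and attrition or
measurement error in the marker instruments.  Passing tests therefore
demonstrate the correctness and calibration of the pipeline's
arithmetic and decision rules under controlled conditions, not clinical
validity on real cohorts.  In particular the generator couples genetics
to cognition only; the empirical association between the PRS and the
cognitive-deficit marker is much stronger here (r ≈ 0.9 between PRS and
liability) than any real cohort would show.

## Numerical and design choices

- One seeded `numpy` generator per run, passed explicitly; sub-streams
  are spawned per stage (`SeedSequence([seed, k])`), so identical
  configurations are bit-reproducible.
- Exclusions carry exactly one primary reason, assigned by the first
  failing rule in a fixed order (missingness → differential missingness
  → HWE → ambiguity → duplication for variants).
- The quartile boundaries use the linear-interpolation percentile
  definition; a degenerate (all-tied) distribution maps everyone to Q1
  with a warning.
- TSV everywhere (tab-safe for allele strings), missing token `NA`,
  headers always; the VCF writer emits minimal unphased GT records and
  the reader (cyvcf2) rejects multi-allelic records with a count.
- Problem sizes in the test suite are scaled to keep the full suite
  fast: QC detection runs at 500 × 2,000, calibration at 500 replicates
  of n = 400, end-to-end pattern recovery over 20 seeds at 2,000
  variants.  Kinship-based tests use ≥1,500 variants because pi-hat
  noise scales as 1/√m and the 0.125 cut-off must sit many SDs above it.

## Known limitations

- The kinship estimator is the simple cross-product method of moments;
  at a few thousand variants its sampling noise approaches the
  third-degree cut-off, and no IBD-segment or robust (KING-type)
  estimator is provided.
- PCA outlier detection assumes outliers are rare and strongly shifted;
  gradual clines are not modelled or detected.
- Wald inference only (no profile-likelihood or exact logistic CIs);
  quasi-separation is flagged, not resolved.
- The LR table ships one revision of the criteria; users tracking a
  different revision must supply their own YAML.
- No multiple-imputation path: all models are complete-case, matching
  the nominal-p reporting convention.
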