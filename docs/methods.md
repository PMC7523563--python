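# Methods

This note documents the models behind radzone, the choices made where the
design was genuinely open, and what the synthetic data does and does not
emulate.

## Genotype model and filters

Genotypes are stored as alternate-allele dosage {0, 1, 2} with NaN for
missing calls; phase is ignored because every statistic in the package
(allele frequencies, heterozygote fractions, dosage correlations, binomial
likelihoods) is phase-free. Locus filters mirror standard RADseq practice:
a locus is kept when its call rate is ≥ 0.8 in every group (both sexes, or
every population) and its whole-dataset heterozygote fraction is ≤ 0.75
(loci above this are typically over-merged paralogs). The per-genotype
coverage filter (≥ 8 reads) properly belongs to the assembly stage, which
is out of scope here; it is applied only when the input carries
per-genotype depth (VCF DP), and skipped with a logged notice otherwise.
Filtering is idempotent by construction.

Transect geography is one-dimensional: `distance_km` runs from 0 at the
northeastern (*B. bufo*) end and increases southwestward, so the focal
(species-B, *B. spinosus*-diagnostic) allele frequency increases with
distance. The cline code assumes this orientation; a decreasing marker
should be re-polarized before fitting.

## Sex-linkage scans

Let H be the heterogametic sex under the hypothesis being tested (males
for XY, females for ZW). For a fixed X/Y (Z/W) difference, H is
heterozygous at every sex-linked SNP and the other sex is homozygous;
the sex-limited allele therefore sits at frequency 1/2 in H and 0
elsewhere.

* **Method I** flags a locus when either allele has frequency within
  `[0.5 − het_freq_tol, 0.5]` in H and at most `hom_freq_max` in the other
  sex. Checking both alleles resolves the tie when the frequency in H is
  exactly 0.5. (The published pipelines describe this criterion only as
  "sex biases in allele frequencies" with heterogametic/homogametic
  thresholds; the sex-limited-allele form used here is the direct genetic
  expectation and maps one threshold onto each sex.)
* **Method II** requires a heterozygote fraction ≥ `het_het_min` in H and
  ≤ `hom_het_max` in the other sex.
* **Method III** operates on tag presence/absence (depth ≥ `min_cov`,
  default 5 reads): present in ≥ `specificity_min` of H and in *zero*
  individuals of the other sex. The zero rule is strict: a single
  presence in the wrong sex disqualifies the tag.

Loci with fewer than `min_informative_per_sex` genotyped individuals of
either sex are not evaluated.

**Permutation significance.** Sex labels are shuffled among sexed samples
(totals preserved) 100 times; the candidate count is significant when it
exceeds the null's 95th percentile. The reported p-value uses the add-one
estimator (1 + #{null ≥ obs}) / (1 + N) so that p is never 0. Across a
threshold grid, the optimal setting minimizes the false-positive
proportion mean(null)/max(obs, 1); ties break toward the larger observed
count, then grid order. The default grid crosses three heterogametic with
two homogametic thresholds for each of methods I and II (full factorial,
36 points) and six specificity values for method III.

**RadSex-style test.** Each tag yields a 2×2 presence × sex table tested
with the Yates-corrected chi-squared (1 df), correction clipped at zero as
is standard. The Bonferroni denominator is the number of *testable* tags —
present in at least one and at most N−1 sexed samples — since constant
tags carry no information; the denominator is recorded in the output.

## Zone statistics

Diagnostic SNPs are fixed differences between the two edge-population
groups: all non-missing genotypes homozygous, opposite alleles, with edge
missingness ≤ 0.1 by default (fixation tolerates missing data, never
polymorphism). One SNP per RAD tag is retained (smallest within-tag index)
to avoid pseudo-replicating a tag. The hybrid index q is the fraction of
species-B alleles over genotyped panel loci — for fixed diagnostic loci
this equals the binomial maximum-likelihood ancestry estimate, and it
stands in for a Bayesian admixture-model Q score (for loci fixed between
the parental groups the two coincide up to sampling noise, so the
heavyweight MCMC clustering step is deliberately not reproduced).
Interspecific heterozygosity is computed on the same non-missing locus
set, giving the classic triangle-plot geometry (F1: q = 0.5, het = 1).

Per population: H_o is the heterozygote fraction averaged over panel loci;
LD is the mean squared Pearson correlation between dosage vectors over all
panel-locus pairs (composite LD, since phase is unknown; zero-variance
pairs are skipped; missing data handled pairwise); admixture LD D′ is the
variance of individual hybrid indices with denominator n (the population
variance; the n vs n−1 choice is undocumented in the sources, so the
simpler moment definition is used and stated). D′ is NaN for
single-individual populations rather than 0.

## Cline model

The core is the standard tension-zone sigmoid

    y(x) = 1 / (1 + exp(−4 (x − c) / w))

with center c and width w = 1/max slope. Exponential introgression tails
(Szymura–Barton parameterization, as used by the cline-fitting packages in
this literature) replace the sigmoid beyond the join points:

    x < c − δ_L:  y(x) = y_L · exp( 4 τ_L (x − c + δ_L) / (w (1 + e^(−4δ_L/w))) ),
                  y_L = 1 / (1 + e^(4δ_L/w))

and mirrored on the right. The tail meets the core continuously at the
join; τ ∈ [0, 1] guarantees y is non-decreasing. Configurations: `none`
(2 parameters), `left`/`right`/`mirror` (4), `both` (6). Frequencies are
scaled by (p_min, p_max), fixed at (0, 1) for diagnostic markers fixed
between edge populations.

A practical identifiability note: the join frequency is y_L =
expit(−4δ/w), so tails with δ ≫ w start where the sigmoid is already
saturated and are statistically invisible at realistic sample sizes.
Detectable introgression corresponds to δ of order w and small τ (slow
decay); the tail simulation studies use that regime (δ/w ≈ 0.3–1,
τ = 0.25).

**Estimation.** The binomial log-likelihood Σ k_i log y(x_i) + (n_i − k_i)
log(1 − y(x_i)) (y clamped to [1e−9, 1 − 1e−9]) is maximized by L-BFGS-B
from multiple starts jittered around moment initials (center from the
0.5-crossing by linear interpolation, width from the 0.2–0.8 crossing
distance). Default bounds: c within the data span ± 50 km, w ∈ [0.1, 2 ×
span], δ ∈ [0, span], τ ∈ [0, 1]. Defaults: 20 starts for single fits, 6
for per-locus batch fits (per-locus fits start from good moment initials,
and their downstream use — parameter distributions and paired tail
comparisons — needs point estimates, not certified global optima). 95%
intervals are profile-likelihood (ΔlogL = 1.92, bisection with
re-optimization); estimation is deterministic given the seed. ML with
profile CIs was chosen over the MCMC of the commonly used R package for
determinism and testability. Mean-ancestry (Q) clines reuse the binomial
machinery with effective counts n_i = 2 × individuals, k_i = round(n_i ·
mean q) — a pseudo-likelihood approximation, stated as such.

Model selection is by AIC = 2k − 2 logL over the five tail configurations,
ties toward fewer parameters, competing among converged fits.
Under-determined inputs (e.g. two populations at frequencies 0 and 1) are
flagged via `converged=False` or `hit_bounds` rather than returned
silently.

**Tail asymmetry.** Across per-locus 6-parameter fits, δ_L vs δ_R and τ_L
vs τ_R are compared with two-sided paired Wilcoxon signed-rank tests
(zero differences dropped; all-zero gives p = 1). Loci whose fits failed
or whose two δ estimates both sit on optimizer bounds are excluded and
counted. At least 6 usable loci are required.

## Synthetic data

`simulate_sexlinked` emulates a two-sex RADseq reference panel: sex-linked
SNPs with the ideal pattern (H heterozygous, other sex homozygous
reference), an autosomal background in Hardy–Weinberg proportions at MAFs
uniform on a configurable range, and sex-specific tags with
Poisson(mean_depth) coverage in H only. Perturbations: symmetric dosage
flips (0↔1, 2↔1, 1→0 or 2 with equal probability) at the genotyping error
rate, uniform missingness, and per-sample tag dropout. Defaults — 20 per
sex, 5,000 autosomal + 20 sex-linked SNPs, 1% error, 5% missing, depth 30,
5% dropout — represent a typical single-species screen. Background
(non-sex-specific) tags are included so the presence/absence contingency
surface and its multiple-testing behavior can be exercised; 10,000-tag
screens are generated for that purpose.

`simulate_zone` emulates a transect: population mean ancestry m(x) follows
the true cline; individual hybrid indices h are Beta-distributed with mean
m(x) and a concentration parameter (default 10) controlling
within-population ancestry spread — this single mechanism produces the
three center signatures simultaneously (ancestry sigmoid, H_o peak,
D′ = Var(h) = m(1−m)/(ν+1) peak) and the triangle-plot geometry, without
modeling explicit pedigree classes (the analyses target populations, not
crosses). Per-locus genotypes are Binomial(2, h) draws in species-B
dosage, with per-locus clines jittered in center (normal) and log-width
(lognormal) around the shared cline; the individual's locus-specific
allele probability is offset by the locus cline's deviation, preserving
admixture LD. mtDNA is a Bernoulli draw from a separate (shifted, tailed)
cline, emulating cyto-nuclear discordance. The default shared cline
(c = 185.9 km, w = 8.6 km on a 0–370 km transect with 21 populations)
represents a narrow tension zone.

What the generator does *not* emulate: linkage between markers beyond
admixture LD (no recombination map), selection against hybrids as a
mechanism (the cline shape is imposed, not emergent), allele-frequency
drift within species, library/batch effects, or non-random missingness.
Passing tests therefore demonstrate correctness of the statistics under
the assumed sampling models, not robustness to those real-data
complications.

`simulate_frequency_tables` draws binomial population counts directly from
cline models (no individuals) for parameter-recovery and asymmetry
studies.

## Study conditions used by the tests and acceptance script

* Sex-linkage recovery: 20M/20F, 5,000 autosomal + 20 sex-linked SNPs, 1%
  error, 5% missing; grid-optimized methods I+II; both XY and mirrored ZW.
* Permutation calibration: 200 pure-autosomal replicates (1,000 loci,
  10M/10F, 100 shuffles each).
* Tag screen: 21M/20F, 20 W-tags among 10,000 tags, depth 30, 5% dropout.
* Single-marker cline recovery: c = 185.9, w = 8.6 km; 30 populations at
  2-km spacing across the transition (156–214 km), 40 alleles each, 100
  replicates. Width information lives in populations on the cline
  shoulders, so the sampling design concentrates populations there, as
  cline-transect designs do.
* Per-locus distributions: 200 loci sharing c = 184, w = 12 km with
  per-locus jitter (sd 2 km, log-sd 0.15), 20 diploids per population on a
  34-population transect (dense 150–220 km center, flanking arms to 0 and
  370 km).
* Tail asymmetry: same transect, 100 alleles per population; calibration
  with mirrored tails (δ = 8, τ = 0.25) over 200 replicates of 25 loci;
  power with δ_L = 4 vs δ_R = 12 (τ = 0.25) at 100 loci.

These sizes keep the full test suite in the minutes range while leaving
each check's statistical resolution intact.

## Known limitations

* Cline tails with δ ≫ w are structurally near-unidentifiable (see above);
  estimates then sit near bounds and are flagged, and the asymmetry test
  drops them.
* Full 6-parameter fits on noisy data shrink the fitted width somewhat
  (typically 10–15% here) because the tail terms absorb shoulder noise;
  per-locus width medians are therefore mildly conservative relative to
  the generating width.
* The profile-CI search re-optimizes nuisance parameters from the MLE
  start only; on ridged likelihoods the interval can be locally rather
  than globally profiled.
* Composite LD r² uses pairwise-complete correlations; under extreme
  missingness different pairs use different individuals.
* The Q-cline pseudo-likelihood understates uncertainty when individual
  ancestries within a population are correlated (which they are, by
  design, at the zone center); its point estimates are unaffected.
* VCF input is read-only and assumes a single alternate allele per record.
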