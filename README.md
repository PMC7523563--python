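# radzone

Sex-linked marker discovery and hybrid-zone cline analysis for RADseq
datasets, built around the *Bufo bufo* / *Bufo spinosus* study system: two
toad species with opposite heterogametic systems (ZW females in *B. bufo*,
XY males in *B. spinosus*) that meet in a narrow tension zone in
southeastern France.

The package is for population geneticists who have (i) a two-sex RADseq
panel and want to diagnose XY vs ZW heterogamety, and/or (ii) a transect of
populations across a hybrid zone and want diagnostic SNPs, hybrid indices,
admixture statistics and geographic cline fits. A synthetic-data module
generates datasets with the statistical structure these analyses assume, so
every stage is testable without sequencing data.

## What it computes

**Sex-linkage scans** (`radzone.sexscan`). Under a hypothesized system the
heterogametic sex H (males for XY, females for ZW) carries one copy of the
sex-limited gametolog, so at a fully sex-linked SNP:

* method I — the sex-limited allele has frequency ≈ 1/2 in H and ≈ 0 in the
  other sex (thresholds: tolerance below 1/2 in H, ceiling in the other);
* method II — heterozygote fraction ≈ 1 in H and ≈ 0 in the other sex;
* method III — a gametolog-specific RAD tag is present in most H
  individuals and in zero individuals of the other sex.

Candidate counts are tested by permutation: sex labels are shuffled
(preserving totals) 100 times and the observed count is compared with the
null's 95th percentile. Across a threshold grid, the optimal setting
minimizes mean null count / observed count (the false-positive proportion).
A RadSex-style analysis tests each raw tag's presence/absence against sex
with a Yates-corrected chi-squared and Bonferroni correction.

**Zone statistics** (`radzone.zonestats`). Diagnostic SNPs are called as
fixed differences between edge populations (one SNP per RAD tag). For an
individual with dosage g_l at L genotyped panel loci, the hybrid index is
q = Σ g_l / 2L (the binomial ML ancestry estimate) and interspecific
heterozygosity is the fraction of panel loci that are heterozygous. Per
population: mean q, observed heterozygosity H_o, composite LD (mean pairwise
r² of dosages), and admixture LD D′ = var(q), which peaks where parental
genomes mix.

**Cline fitting** (`radzone.clinefit`). Population frequencies p(x) along a
transect follow the sigmoid y(x) = 1/(1 + exp(−4(x−c)/w)) with center c and
width w (inverse maximum slope), optionally extended by exponential
introgression tails of length δ and slope τ per side (Szymura–Barton form).
Fitting maximizes the binomial likelihood (bounded multistart), 95% CIs come
from profile likelihood (ΔlogL = 1.92), tail configurations (2-, 4- or
6-parameter) are compared by AIC, and tail asymmetry across loci is tested
with paired Wilcoxon signed-rank tests on (δ_L, δ_R) and (τ_L, τ_R).

## Worked example

```python
import numpy as np
from radzone import (
    SexLinkSimConfig, simulate_sexlinked, ScanParams,
    scan_method_I, scan_method_II, permutation_test,
)

g, tags, meta, truth = simulate_sexlinked(SexLinkSimConfig(
    n_males=20, n_females=20, n_autosomal=5000, n_sexlinked_snps=20,
    genotyping_error_rate=0.01, missing_rate=0.05, system="XY", seed=1,
))
params = ScanParams(het_freq_tol=0.1, hom_freq_max=0.05)
hits = scan_method_I(g, meta, "XY", params)
pr = permutation_test(lambda m: scan_method_I(g, m, "XY", params), meta,
                      n_permutations=100, seed=1)
print(len(hits), sorted(hits)[:3])
print(pr.observed_count, pr.percentile95, round(pr.p_value, 4), pr.significant)
```

prints

```
18 ['SL1', 'SL10', 'SL11']
18 0.0 0.0099 True
```

18 of the 20 planted sex-linked SNPs are flagged under the XY hypothesis at
these thresholds (genotyping error pushes the other two just outside the
allele-frequency window; method II catches them); no shuffled-label
replicate flags any locus (95th percentile 0), so the count is significant
at p = 1/101 ≈ 0.0099 (the add-one permutation estimate).

The same round trip for clines:

```python
from radzone import ClineModel, simulate_frequency_tables, fit_cline

truth = ClineModel(c=185.9, w=8.6)
tab = simulate_frequency_tables([truth], np.linspace(156, 214, 30), 40, seed=1)[0]
fit = fit_cline(tab, "none", seed=1)
print(round(fit.model.c, 1), round(fit.model.w, 1))
print({k: tuple(round(v, 1) for v in ci) for k, ci in fit.ci.items()})
```

prints

```
185.7 8.6
{'c': (185.1, 186.3), 'w': (7.3, 10.1)}
```

i.e. a 30-population transect with 40 alleles per population recovers the
center to a fraction of a km and the width within the profile CI.

There is also a CLI mirroring the pipeline stages
(`radzone simulate-sexlink`, `scan-sex`, `radsex-test`, `call-diagnostics`,
`zone-stats`, `fit-cline`, `fit-loci`, `run <config>`); see
`radzone --help`.

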