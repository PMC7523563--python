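"""Synthetic genotype, tag and transect data with the statistical structure
the downstream analyses assume.

Two generators are provided.  :func:`simulate_sexlinked` emulates a
two-sex RADseq screen: fully sex-linked SNPs (the heterogametic sex is
always heterozygous, the homogametic sex homozygous), an autosomal
background in Hardy-Weinberg proportions, and sex-specific RAD tags subject
to dropout, all perturbed by a symmetric genotyping-error model and random
missingness.  :func:`simulate_zone` emulates a hybrid-zone transect:
population mean ancestry follows a geographic cline, individual hybrid
indices are Beta-distributed around that mean (which creates admixture
linkage disequilibrium and a heterozygosity peak at the zone center), and
diagnostic-locus genotypes are binomial draws from the individual index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clinefit import ClineModel, cline_value
from .io_formats import (
    GenotypeMatrix,
    LocusInfo,
    TagMatrix,
    make_frequency_table,
    make_meta,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SexLinkSimConfig:
    """Conditions for the two-sex marker screen.

    Defaults mirror a typical single-species RADseq reference panel:
    20 individuals of each sex, a few thousand autosomal SNPs, a handful of
    fully sex-linked SNPs and sex-specific tags, ~1% genotyping error and
    ~5% missing calls, mean tag depth 30 reads with 5% allelic dropout.
    """

    n_males: int = 20
    n_females: int = 20
    n_autosomal: int = 5000
    n_sexlinked_snps: int = 20
    n_sex_specific_tags: int = 10
    n_background_tags: int = 100
    system: str = "XY"
    autosomal_maf_range: tuple[float, float] = (0.05, 0.5)
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.05
    tag_dropout_rate: float = 0.05
    mean_depth: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one sample of each sex")
        if self.system not in ("XY", "ZW"):
            raise ValueError("system must be 'XY' or 'ZW'")
        lo, hi = self.autosomal_maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("autosomal_maf_range must lie within [0, 0.5]")
        for name in ("genotyping_error_rate", "missing_rate", "tag_dropout_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for name in ("n_autosomal", "n_sexlinked_snps", "n_sex_specific_tags",
                     "n_background_tags"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _random_tags(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(_BASES, size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def _perturb(rng: np.random.Generator, dosage: np.ndarray, error_rate: float,
             missing_rate: float) -> np.ndarray:
    """Symmetric dosage-flip errors (0<->1, 2<->1, 1->0 or 2) then missingness."""
    out = dosage.astype(float).copy()
    if error_rate > 0:
        flip = rng.random(out.shape) < error_rate
        updown = rng.random(out.shape) < 0.5  # direction for heterozygotes
        new = out.copy()
        new[flip & (out == 0)] = 1
        new[flip & (out == 2)] = 1
        new[flip & (out == 1) & updown] = 0
        new[flip & (out == 1) & ~updown] = 2
        out = new
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = np.nan
    return out


def simulate_sexlinked(config: SexLinkSimConfig):
    """Generate a sexed genotype + tag dataset with known sex-linkage truth.

    Returns ``(genotypes, tags, meta, truth)`` where ``truth`` maps
    ``"sexlinked_loci"``, ``"autosomal_loci"``, ``"sex_specific_tags"`` and
    ``"background_tags"`` to id lists.  Before error/missing perturbation,
    every sex-linked SNP is heterozygous (dosage 1) in the heterogametic sex
    and homozygous reference (dosage 0) in the homogametic sex.  Sex-specific
    tags have Poisson(mean_depth) depth in the heterogametic sex only, with
    per-sample dropout; background tags are shared by both sexes.
    """
    rng = np.random.default_rng(config.seed)
    males = [f"M{i + 1}" for i in range(config.n_males)]
    females = [f"F{i + 1}" for i in range(config.n_females)]
    samples = males + females
    n = len(samples)
    sex = np.array(["M"] * config.n_males + ["F"] * config.n_females)
    het_sex = "M" if config.system == "XY" else "F"
    is_het_sex = sex == het_sex

    blocks = []
    loci: list[LocusInfo] = []
    sexlinked_ids, autosomal_ids = [], []

    if config.n_sexlinked_snps:
        sl = np.where(is_het_sex, 1.0, 0.0)[None, :].repeat(config.n_sexlinked_snps, 0)
        blocks.append(sl)
        for i in range(config.n_sexlinked_snps):
            lid = f"SL{i + 1}"
            sexlinked_ids.append(lid)
            loci.append(LocusInfo(lid, tag_id=f"tagSL{i + 1}", snp_index_in_tag=0))

    if config.n_autosomal:
        lo, hi = config.autosomal_maf_range
        maf = rng.uniform(lo, hi, size=config.n_autosomal)
        auto = rng.binomial(2, maf[:, None], size=(config.n_autosomal, n)).astype(float)
        blocks.append(auto)
        for i in range(config.n_autosomal):
            lid = f"A{i + 1}"
            autosomal_ids.append(lid)
            loci.append(LocusInfo(lid, tag_id=f"tagA{i + 1}", snp_index_in_tag=0))

    dosage = np.vstack(blocks) if blocks else np.empty((0, n))
    dosage = _perturb(rng, dosage, config.genotyping_error_rate, config.missing_rate)
    genotypes = GenotypeMatrix(loci=loci, samples=samples, dosage=dosage)

    n_tags = config.n_sex_specific_tags + config.n_background_tags
    tag_seqs = _random_tags(rng, n_tags)
    depth = np.zeros((n_tags, n), dtype=int)
    k = config.n_sex_specific_tags
    if k:
        d = rng.poisson(config.mean_depth, size=(k, n))
        kept = rng.random((k, n)) >= config.tag_dropout_rate
        depth[:k] = np.where(is_het_sex[None, :] & kept, d, 0)
    if config.n_background_tags:
        d = rng.poisson(config.mean_depth, size=(config.n_background_tags, n))
        kept = rng.random((config.n_background_tags, n)) >= config.tag_dropout_rate
        depth[k:] = np.where(kept, d, 0)
    tags = TagMatrix(tags=tag_seqs, samples=samples, depth=depth)

    meta = make_meta(
        pd.DataFrame(
            {
                "sample_id": samples,
                "sex": sex,
                "population_id": "ref",
                "distance_km": 0.0,
                "mitotype": "unknown",
            }
        )
    )
    truth = {
        "system": config.system,
        "sexlinked_loci": sexlinked_ids,
        "autosomal_loci": autosomal_ids,
        "sex_specific_tags": tag_seqs[:k],
        "background_tags": tag_seqs[k:],
    }
    return genotypes, tags, meta, truth


@dataclass
class ZoneSimConfig:
    """Conditions for the hybrid-zone transect.

    The default transect spans 0-370 km with populations every ~18 km, a
    shared true cline of width ~9 km centered near 186 km (a narrow tension
    zone), 30 diagnostic loci with mild per-locus center/width jitter, and a
    within-population Beta concentration of 10 for individual hybrid indices.
    The mtDNA cline defaults to the nuclear cline shifted ~18 km toward the
    species-B side with a tail on that side (cyto-nuclear discordance).
    """

    pop_positions_km: tuple[float, ...] = tuple(float(x) for x in np.linspace(0, 370, 21))
    n_ind_per_pop: int = 10
    n_diagnostic_loci: int = 30
    true_cline: ClineModel = field(
        default_factory=lambda: ClineModel(c=185.9, w=8.6, tail_config="none")
    )
    per_locus_center_sd_km: float = 0.0
    per_locus_width_logsd: float = 0.0
    hybrid_index_concentration: float = 10.0
    mtdna_cline: ClineModel = field(
        default_factory=lambda: ClineModel(
            c=203.6, w=11.4, tail_config="left", delta_L=40.0, tau_L=0.6
        )
    )
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        pos = np.asarray(self.pop_positions_km, dtype=float)
        if len(pos) < 2 or not (np.diff(pos) > 0).all():
            raise ValueError("pop_positions_km must be strictly increasing")
        if self.n_ind_per_pop < 1 or self.n_diagnostic_loci < 1:
            raise ValueError("need >= 1 individual per population and >= 1 locus")
        if self.per_locus_center_sd_km < 0 or self.per_locus_width_logsd < 0:
            raise ValueError("per-locus jitter parameters must be >= 0")
        if self.hybrid_index_concentration <= 0:
            raise ValueError("hybrid_index_concentration must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _beta_hybrid_index(rng, mean, concentration, size):
    """h ~ Beta with the given mean; degenerate means give point masses."""
    m = np.broadcast_to(np.asarray(mean, dtype=float), size)
    out = np.empty(size)
    interior = (m > 0) & (m < 1)
    out[~interior] = m[~interior]
    if interior.any():
        a = m[interior] * concentration
        b = (1 - m[interior]) * concentration
        out[interior] = rng.beta(a, b)
    return out


def simulate_zone(config: ZoneSimConfig):
    """Generate a transect dataset with known per-locus cline truth.

    Returns ``(genotypes, meta, freq_tables, truth)``.  ``freq_tables`` maps
    locus_id to a population allele-frequency table (counts observed in the
    simulated genotypes); ``truth`` carries the shared and per-locus
    :class:`ClineModel` objects and the drawn individual hybrid indices.
    Genotypes are coded as species-B diagnostic allele dosage.
    """
    rng = np.random.default_rng(config.seed)
    positions = np.asarray(config.pop_positions_km, dtype=float)
    n_pops = len(positions)
    n_ind = n_pops * config.n_ind_per_pop
    L = config.n_diagnostic_loci

    # per-locus true clines: jitter center and log-width around the shared cline
    centers = config.true_cline.c + rng.normal(0, config.per_locus_center_sd_km, L)
    widths = config.true_cline.w * np.exp(rng.normal(0, config.per_locus_width_logsd, L))
    locus_clines = [replace(config.true_cline, c=centers[i], w=widths[i]) for i in range(L)]

    pop_ids = [f"pop{i + 1}" for i in range(n_pops)]
    sample_ids, sample_pop, sample_x = [], [], []
    for pid, x in zip(pop_ids, positions):
        for j in range(config.n_ind_per_pop):
            sample_ids.append(f"{pid}_i{j + 1}")
            sample_pop.append(pid)
            sample_x.append(x)
    sample_x = np.asarray(sample_x)

    m = cline_value(sample_x, config.true_cline)  # mean ancestry per individual's pop
    h = _beta_hybrid_index(rng, m, config.hybrid_index_concentration, (n_ind,))

    # per-locus allele probability: individual index shifted by the locus
    # cline's deviation from the shared cline at that position
    shared = cline_value(sample_x, config.true_cline)
    dosage = np.empty((L, n_ind))
    for l in range(L):
        offset = cline_value(sample_x, locus_clines[l]) - shared
        p = np.clip(h + offset, 0.0, 1.0)
        dosage[l] = rng.binomial(2, p)
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan

    loci = [LocusInfo(f"D{l + 1}", tag_id=f"tagD{l + 1}", snp_index_in_tag=0)
            for l in range(L)]
    genotypes = GenotypeMatrix(loci=loci, samples=sample_ids, dosage=dosage)

    mito_p = cline_value(positions, config.mtdna_cline)
    mito_by_pop = {}
    for pid, p in zip(pop_ids, mito_p):
        draws = rng.random(config.n_ind_per_pop) < p
        mito_by_pop[pid] = np.where(draws, "B", "A")
    mitotypes = []
    counters = {pid: 0 for pid in pop_ids}
    for pid in sample_pop:
        mitotypes.append(mito_by_pop[pid][counters[pid]])
        counters[pid] += 1

    meta = make_meta(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "sex": "unknown",
                "population_id": sample_pop,
                "distance_km": sample_x,
                "mitotype": mitotypes,
            }
        )
    )

    freq_tables = {}
    pop_index = {pid: np.array([s == pid for s in sample_pop]) for pid in pop_ids}
    for l, li in enumerate(loci):
        rows = []
        for pid, x in zip(pop_ids, positions):
            vals = dosage[l, pop_index[pid]]
            called = ~np.isnan(vals)
            rows.append(
                {
                    "population_id": pid,
                    "distance_km": x,
                    "n_alleles": int(2 * called.sum()),
                    "focal_allele_count": int(np.nansum(vals[called])),
                }
            )
        tab = pd.DataFrame(rows)
        tab = tab[tab["n_alleles"] > 0]
        freq_tables[li.locus_id] = make_frequency_table(tab)

    truth = {
        "shared_cline": config.true_cline,
        "locus_clines": {li.locus_id: cm for li, cm in zip(loci, locus_clines)},
        "mtdna_cline": config.mtdna_cline,
        "hybrid_index": pd.Series(h, index=sample_ids),
    }
    return genotypes, meta, freq_tables, truth


def simulate_frequency_tables(
    models: list[ClineModel],
    positions_km: np.ndarray,
    n_alleles_per_pop: int,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Draw binomial population frequency tables directly from cline models.

    Lighter-weight than :func:`simulate_zone` (no individuals): for each model
    and population, ``focal_allele_count ~ Binomial(n, cline_value(x))``.
    Used for cline parameter-recovery and tail-asymmetry studies.
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions_km, dtype=float)
    out = []
    for m in models:
        p = cline_value(positions, m)
        counts = rng.binomial(n_alleles_per_pop, p)
        out.append(
            make_frequency_table(
                pd.DataFrame(
                    {
                        "population_id": [f"pop{i + 1}" for i in range(len(positions))],
                        "distance_km": positions,
                        "n_alleles": n_alleles_per_pop,
                        "focal_allele_count": counts,
                    }
                )
            )
        )
    return out
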