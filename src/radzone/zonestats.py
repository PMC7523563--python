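"""Species-diagnostic SNP calling and admixture statistics for a hybrid-zone
transect.

Diagnostic SNPs are those fixed for alternative alleles between the
reference populations at the two edges of the study area (edge group A:
B. spinosus side; edge group B: B. bufo side... polarity is recorded so that
a hybrid index of 1 means pure species B).  From a diagnostic panel this
module computes, per individual, the maximum-likelihood hybrid index (the
fraction of species-B diagnostic alleles — the binomial ML estimate of
ancestry, a direct proxy for an admixture-model Q score on fixed loci) and
interspecific heterozygosity; and per population, mean ancestry, observed
heterozygosity Ho, composite linkage disequilibrium (mean squared genotypic
correlation over locus pairs) and admixture linkage disequilibrium D'
measured as the variance of individual hybrid indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

logger = logging.getLogger("radzone")


@dataclass
class DiagnosticPanel:
    """Loci fixed between the edge populations, with allele polarity.

    ``polarity[locus_id]`` is +1 if the alternate (dosage-counted) allele is
    the species-B diagnostic allele, -1 if the reference allele is.  At most
    one SNP per RAD tag is retained.
    """

    loci: list[str]
    polarity: dict[str, int]
    edge_pops_A: list[str] = field(default_factory=list)
    edge_pops_B: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loci)


def call_diagnostic_snps(
    g: GenotypeMatrix,
    meta: pd.DataFrame,
    edge_pops_A: list[str],
    edge_pops_B: list[str],
    max_missing_in_edges: float = 0.1,
) -> DiagnosticPanel:
    """Call SNPs fixed between the two edge-population groups.

    A locus qualifies when every non-missing genotype in edge group A is
    homozygous for one allele, every non-missing genotype in edge group B is
    homozygous for the other, and the missing fraction within each edge
    group is at most ``max_missing_in_edges``.  One SNP per RAD tag is kept
    (smallest ``snp_index_in_tag``).  Output is invariant to sample and
    locus order.
    """
    pops = meta.set_index("sample_id")["population_id"].reindex(g.samples)
    mask_A = pops.isin(edge_pops_A).to_numpy()
    mask_B = pops.isin(edge_pops_B).to_numpy()
    if mask_A.sum() == 0 or mask_B.sum() == 0:
        raise ValueError("both edge groups must contain samples")

    dA = g.dosage[:, mask_A]
    dB = g.dosage[:, mask_B]
    missA = np.isnan(dA).mean(axis=1)
    missB = np.isnan(dB).mean(axis=1)
    nA = (~np.isnan(dA)).sum(axis=1)
    nB = (~np.isnan(dB)).sum(axis=1)

    with np.errstate(invalid="ignore"):
        a_all0 = np.all(np.isnan(dA) | (dA == 0.0), axis=1) & (nA > 0)
        a_all2 = np.all(np.isnan(dA) | (dA == 2.0), axis=1) & (nA > 0)
        b_all0 = np.all(np.isnan(dB) | (dB == 0.0), axis=1) & (nB > 0)
        b_all2 = np.all(np.isnan(dB) | (dB == 2.0), axis=1) & (nB > 0)

    fixed_alt_in_B = a_all0 & b_all2  # B carries the alternate allele
    fixed_ref_in_B = a_all2 & b_all0
    qualifies = (
        (fixed_alt_in_B | fixed_ref_in_B)
        & (missA <= max_missing_in_edges)
        & (missB <= max_missing_in_edges)
    )

    # one SNP per tag, smallest snp_index_in_tag; deterministic in locus order
    chosen: dict[str, int] = {}
    for i in np.flatnonzero(qualifies):
        li = g.loci[i]
        prev = chosen.get(li.tag_id)
        if prev is None or (
            li.snp_index_in_tag < g.loci[prev].snp_index_in_tag
        ):
            chosen[li.tag_id] = i

    idx = sorted(chosen.values(), key=lambda i: g.loci[i].locus_id)
    loci = [g.loci[i].locus_id for i in idx]
    polarity = {
        g.loci[i].locus_id: (1 if fixed_alt_in_B[i] else -1) for i in idx
    }
    if not loci:
        logger.warning("no diagnostic SNP found between edge groups")
    return DiagnosticPanel(
        loci=loci,
        polarity=polarity,
        edge_pops_A=list(edge_pops_A),
        edge_pops_B=list(edge_pops_B),
    )


@dataclass
class IndividualAdmixture:
    """Hybrid index and interspecific heterozygosity for one individual."""

    sample_id: str
    hybrid_index_q: float
    interspecific_het: float
    n_loci_used: int


def _panel_dosage(g: GenotypeMatrix, panel: DiagnosticPanel) -> np.ndarray:
    """Panel loci x samples matrix of species-B allele dosage."""
    pos = {lid: i for i, lid in enumerate(g.locus_ids)}
    try:
        rows = [pos[lid] for lid in panel.loci]
    except KeyError as e:
        raise KeyError(f"panel locus {e.args[0]!r} not in genotype matrix") from None
    d = g.dosage[rows].copy()
    flip = np.array([panel.polarity[lid] for lid in panel.loci]) == -1
    d[flip] = 2.0 - d[flip]
    return d


def hybrid_index(
    g: GenotypeMatrix, panel: DiagnosticPanel, sample: str
) -> IndividualAdmixture | None:
    """Per-individual ancestry from diagnostic allele counts.

    ``q`` is the fraction of species-B alleles over genotyped panel loci —
    the binomial maximum-likelihood ancestry estimate — and
    ``interspecific_het`` the fraction of those loci that are heterozygous.
    Returns None when no panel locus is genotyped in the sample.
    """
    col = g.sample_columns([sample])[0]
    d = _panel_dosage(g, panel)[:, col]
    called = ~np.isnan(d)
    n = int(called.sum())
    if n == 0:
        return None
    q = float(np.nansum(d[called]) / (2.0 * n))
    het = float((d[called] == 1.0).mean())
    return IndividualAdmixture(sample, q, het, n)


def admixture_table(
    g: GenotypeMatrix, panel: DiagnosticPanel, meta: pd.DataFrame
) -> pd.DataFrame:
    """Hybrid index and interspecific heterozygosity for every sample."""
    d = _panel_dosage(g, panel)
    called = ~np.isnan(d)
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n > 0, np.nansum(d, axis=0) / (2.0 * np.maximum(n, 1)), np.nan)
        het = np.where(n > 0, np.nansum(d == 1.0, axis=0) / np.maximum(n, 1), np.nan)
    out = pd.DataFrame(
        {
            "sample_id": g.samples,
            "hybrid_index_q": q,
            "interspecific_het": het,
            "n_loci_used": n,
        }
    )
    return out.merge(meta[["sample_id", "population_id", "distance_km"]], on="sample_id")


def _mean_pairwise_r2(d: np.ndarray) -> float:
    """Mean squared Pearson correlation over locus pairs (composite LD).

    Missing data handled pairwise; zero-variance pairs are skipped.
    Returns NaN when no pair is informative.
    """
    L = d.shape[0]
    if L < 2:
        return np.nan
    corr = pd.DataFrame(d.T).corr()  # pairwise-complete, NaN on zero variance
    vals = corr.to_numpy()
    iu = np.triu_indices(L, k=1)
    r = vals[iu]
    r = r[~np.isnan(r)]
    if r.size == 0:
        return np.nan
    return float(np.mean(r**2))


def population_summaries(
    g: GenotypeMatrix, panel: DiagnosticPanel, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-population admixture statistics along the transect.

    For each population: ``mean_q``; ``Ho`` (observed heterozygosity, the
    heterozygote fraction averaged over panel loci); ``ld_r2`` (mean squared
    genotypic correlation over all panel-locus pairs); ``admix_ld_Dprime``
    (variance of individual hybrid indices, denominator n — NaN for
    single-individual populations).  Ho and D' both peak where parental
    genomes mix, i.e. at the zone center.
    """
    d = _panel_dosage(g, panel)
    adm = admixture_table(g, panel, meta)
    pops = meta.set_index("sample_id")["population_id"].reindex(g.samples).to_numpy()
    rows = []
    for pid, grp in adm.groupby("population_id", sort=False):
        cols = pops == pid
        dp = d[:, cols]
        called = ~np.isnan(dp)
        with np.errstate(invalid="ignore", divide="ignore"):
            het_per_locus = np.where(
                called.sum(axis=1) > 0,
                np.nansum(dp == 1.0, axis=1) / np.maximum(called.sum(axis=1), 1),
                np.nan,
            )
        q = grp["hybrid_index_q"].dropna().to_numpy()
        rows.append(
            {
                "population_id": pid,
                "distance_km": float(grp["distance_km"].iloc[0]),
                "n": int(cols.sum()),
                "mean_q": float(np.mean(q)) if q.size else np.nan,
                "Ho": float(np.nanmean(het_per_locus)),
                "ld_r2": _mean_pairwise_r2(dp),
                "admix_ld_Dprime": float(np.var(q)) if q.size >= 2 else np.nan,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("distance_km", kind="stable")
        .reset_index(drop=True)
    )
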