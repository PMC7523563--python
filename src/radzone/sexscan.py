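"""Sex-linked marker discovery from genotype and tag-presence matrices.

Three complementary criteria flag candidate markers, each evaluated under a
hypothesized heterogametic system (XY: males heterogametic; ZW: females):

* method I — allele frequencies: the sex-limited allele (Y- or W-borne)
  should sit near frequency 1/2 in the heterogametic sex and near 0 in the
  homogametic sex;
* method II — heterozygosity: a fixed X/Y (Z/W) difference makes the
  heterogametic sex consistently heterozygous and the homogametic sex
  homozygous;
* method III — tag dropout: a Y- (W-)specific RAD tag is present in most
  heterogametic-sex individuals and absent from every homogametic-sex one.

Because relaxed thresholds admit false positives, significance of a
candidate count is assessed by permutation: sex labels are shuffled
(preserving sex totals), the scan repeated, and the observed count compared
with the 95th percentile of the null counts.  Across a threshold grid, the
optimal setting minimizes the mean null count relative to the observed
count.  A RadSex-style analysis of the raw tag-presence matrix (per-tag
Yates chi-squared with Bonferroni correction) complements the scans without
requiring locus assembly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

SYSTEMS = ("XY", "ZW")
METHODS = ("I", "II", "III")


@dataclass(frozen=True)
class ScanParams:
    """Thresholds for the three scan criteria.

    ``het_freq_tol``/``hom_freq_max`` are method I's heterogametic and
    homogametic thresholds; ``het_het_min``/``hom_het_max`` method II's;
    ``specificity_min`` method III's sex-specificity threshold.  Loci with
    fewer than ``min_informative_per_sex`` genotyped samples of either sex
    are not evaluated.
    """

    het_freq_tol: float = 0.05
    hom_freq_max: float = 0.05
    het_het_min: float = 0.9
    hom_het_max: float = 0.05
    specificity_min: float = 0.9
    min_informative_per_sex: int = 5

    def __post_init__(self):
        if not 0 <= self.het_freq_tol <= 0.5:
            raise ValueError("het_freq_tol must be in [0, 0.5]")
        if not 0 <= self.hom_freq_max <= 0.5:
            raise ValueError("hom_freq_max must be in [0, 0.5]")
        if not 0 < self.het_het_min <= 1:
            raise ValueError("het_het_min must be in (0, 1]")
        if not 0 <= self.hom_het_max < 1:
            raise ValueError("hom_het_max must be in [0, 1)")
        if self.het_het_min <= self.hom_het_max:
            raise ValueError("het_het_min must exceed hom_het_max")
        if not 0 < self.specificity_min <= 1:
            raise ValueError("specificity_min must be in (0, 1]")
        if self.min_informative_per_sex < 1:
            raise ValueError("min_informative_per_sex must be >= 1")


def default_param_grid() -> list[ScanParams]:
    """The default threshold grid: the full factorial over method I's
    heterogametic/homogametic thresholds (3x2) and method II's (3x2), with
    method III's six specificity values cycled across the grid points."""
    freq_tols = (0.05, 0.1, 0.2)
    freq_maxs = (0.01, 0.05)
    het_mins = (0.75, 0.9, 1.0)
    het_maxs = (0.05, 0.1)
    specs = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    grid = []
    combos = list(itertools.product(freq_tols, freq_maxs, het_mins, het_maxs))
    for i, (ft, fm, hm, hx) in enumerate(combos):
        grid.append(
            ScanParams(
                het_freq_tol=ft,
                hom_freq_max=fm,
                het_het_min=hm,
                hom_het_max=hx,
                specificity_min=specs[i % len(specs)],
            )
        )
    return grid


def _sex_masks(meta: pd.DataFrame, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    sex = meta.set_index("sample_id")["sex"].reindex(samples).to_numpy()
    return sex == "M", sex == "F"


def _het_hom_masks(system: str, male_mask, female_mask):
    if system == "XY":
        return male_mask, female_mask
    if system == "ZW":
        return female_mask, male_mask
    raise ValueError("system must be 'XY' or 'ZW'")


def locus_diagnostics(
    g: GenotypeMatrix, male_mask: np.ndarray, female_mask: np.ndarray
) -> pd.DataFrame:
    """Per-locus, per-sex allele frequencies and heterozygote fractions."""
    out = {}
    for label, mask in (("M", male_mask), ("F", female_mask)):
        d = g.dosage[:, mask]
        called = ~np.isnan(d)
        n = called.sum(axis=1)
        alt = np.nansum(d, axis=1)
        het = np.nansum(d == 1.0, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"n_{label}"] = n
            out[f"alt_freq_{label}"] = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
            out[f"het_frac_{label}"] = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return pd.DataFrame(out, index=g.locus_ids)


def _informative(diag: pd.DataFrame, params: ScanParams) -> np.ndarray:
    return (
        (diag["n_M"].to_numpy() >= params.min_informative_per_sex)
        & (diag["n_F"].to_numpy() >= params.min_informative_per_sex)
    )


def scan_method_I(
    g: GenotypeMatrix,
    meta: pd.DataFrame,
    system: str = "XY",
    params: ScanParams | None = None,
) -> list[str]:
    """Allele-frequency criterion: flags loci whose minor allele in the
    heterogametic sex has frequency within ``[0.5 - het_freq_tol, 0.5]``
    there and at most ``hom_freq_max`` in the homogametic sex.

    Both alleles are examined, so a frequency tie at exactly 0.5 resolves
    toward whichever allele is rare in the homogametic sex.  Samples of
    unknown sex are excluded.
    """
    params = params or ScanParams()
    male, female = _sex_masks(meta, g.samples)
    diag = locus_diagnostics(g, male, female)
    hs = "M" if system == "XY" else "F"
    os_ = "F" if system == "XY" else "M"
    if system not in SYSTEMS:
        raise ValueError("system must be 'XY' or 'ZW'")
    ok = _informative(diag, params)
    flagged = np.zeros(len(diag), dtype=bool)
    f_het = diag[f"alt_freq_{hs}"].to_numpy()
    f_hom = diag[f"alt_freq_{os_}"].to_numpy()
    lo = 0.5 - params.het_freq_tol
    for freq_h, freq_o in ((f_het, f_hom), (1.0 - f_het, 1.0 - f_hom)):
        with np.errstate(invalid="ignore"):
            flagged |= (freq_h >= lo) & (freq_h <= 0.5) & (freq_o <= params.hom_freq_max)
    return [lid for lid, f, o in zip(g.locus_ids, flagged, ok) if f and o]


def scan_method_II(
    g: GenotypeMatrix,
    meta: pd.DataFrame,
    system: str = "XY",
    params: ScanParams | None = None,
) -> list[str]:
    """Heterozygosity criterion: heterozygote fraction at least
    ``het_het_min`` in the heterogametic sex and at most ``hom_het_max`` in
    the homogametic sex."""
    params = params or ScanParams()
    if system not in SYSTEMS:
        raise ValueError("system must be 'XY' or 'ZW'")
    male, female = _sex_masks(meta, g.samples)
    diag = locus_diagnostics(g, male, female)
    hs = "M" if system == "XY" else "F"
    os_ = "F" if system == "XY" else "M"
    ok = _informative(diag, params)
    with np.errstate(invalid="ignore"):
        flagged = (
            (diag[f"het_frac_{hs}"].to_numpy() >= params.het_het_min)
            & (diag[f"het_frac_{os_}"].to_numpy() <= params.hom_het_max)
        )
    return [lid for lid, f, o in zip(g.locus_ids, flagged, ok) if f and o]


def scan_method_III(
    presence: np.ndarray,
    tags: list[str],
    meta: pd.DataFrame,
    samples: list[str],
    system: str = "XY",
    params: ScanParams | None = None,
) -> list[str]:
    """Tag-dropout criterion: flags tags present in at least
    ``specificity_min`` of heterogametic-sex individuals and in **zero**
    homogametic-sex individuals (strict absence)."""
    params = params or ScanParams()
    if system not in SYSTEMS:
        raise ValueError("system must be 'XY' or 'ZW'")
    male, female = _sex_masks(meta, samples)
    het_mask, hom_mask = _het_hom_masks(system, male, female)
    if het_mask.sum() == 0 or hom_mask.sum() == 0:
        raise ValueError("both sexes must be represented")
    frac_het = presence[:, het_mask].mean(axis=1)
    any_hom = presence[:, hom_mask].any(axis=1)
    flagged = (frac_het >= params.specificity_min) & ~any_hom
    return [t for t, f in zip(tags, flagged) if f]


@dataclass
class ScanResult:
    """Candidates per system and method, with per-marker diagnostics."""

    candidates: dict[str, dict[str, list[str]]]
    diagnostics: pd.DataFrame | None = None

    @property
    def counts(self) -> dict[str, dict[str, int]]:
        return {
            sys: {m: len(ids) for m, ids in by_m.items()}
            for sys, by_m in self.candidates.items()
        }

    def union(self, system: str, methods=("I", "II")) -> set[str]:
        return set().union(*(self.candidates[system].get(m, []) for m in methods))


def scan_all(
    g: GenotypeMatrix | None,
    meta: pd.DataFrame,
    params: ScanParams | None = None,
    presence: np.ndarray | None = None,
    tags: list[str] | None = None,
    tag_samples: list[str] | None = None,
    systems=SYSTEMS,
) -> ScanResult:
    """Run every applicable scan for each hypothesized system."""
    params = params or ScanParams()
    candidates: dict[str, dict[str, list[str]]] = {}
    diag = None
    for system in systems:
        by_m: dict[str, list[str]] = {}
        if g is not None:
            by_m["I"] = scan_method_I(g, meta, system, params)
            by_m["II"] = scan_method_II(g, meta, system, params)
        if presence is not None:
            by_m["III"] = scan_method_III(
                presence, tags, meta, tag_samples, system, params
            )
        candidates[system] = by_m
    if g is not None:
        male, female = _sex_masks(meta, g.samples)
        diag = locus_diagnostics(g, male, female)
    return ScanResult(candidates=candidates, diagnostics=diag)


@dataclass
class PermutationResult:
    """Observed candidate count against a shuffled-sex null distribution.

    ``p_value`` uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)``; ``significant``
    requires the observed count to exceed the null's 95th percentile.
    ``optimality_score`` (mean null count / max(observed, 1)) is the
    false-positive proportion minimized during threshold selection.
    """

    observed_count: int
    null_counts: list[int]
    p_value: float
    percentile95: float
    optimality_score: float
    significant: bool


def _shuffle_meta(meta: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Permute sex labels among sexed samples, preserving the M/F totals."""
    out = meta.copy()
    sexed = out["sex"].isin(("M", "F")).to_numpy()
    labels = out.loc[sexed, "sex"].to_numpy()
    out.loc[sexed, "sex"] = rng.permutation(labels)
    return out


def permutation_test(
    scan,
    meta: pd.DataFrame,
    n_permutations: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Assess significance of a scan's candidate count by sex-label shuffling.

    ``scan`` is a callable ``meta -> candidate list`` (e.g. a closure over a
    genotype matrix, system and thresholds); it is run once on the observed
    labels and once per shuffled replicate.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = len(scan(meta))
    rng = np.random.default_rng(seed)
    null_counts = [len(scan(_shuffle_meta(meta, rng))) for _ in range(n_permutations)]
    null = np.asarray(null_counts)
    p95 = float(np.percentile(null, 95))
    p = float((1 + (null >= observed).sum()) / (1 + n_permutations))
    return PermutationResult(
        observed_count=observed,
        null_counts=null_counts,
        p_value=p,
        percentile95=p95,
        optimality_score=float(null.mean() / max(observed, 1)),
        significant=bool(observed > p95),
    )


def optimize_params(
    g: GenotypeMatrix | None,
    meta: pd.DataFrame,
    system: str,
    param_grid: list[ScanParams] | None = None,
    method: str = "I",
    n_permutations: int = 100,
    seed: int = 0,
    presence: np.ndarray | None = None,
    tags: list[str] | None = None,
    tag_samples: list[str] | None = None,
):
    """Pick the threshold setting with the lowest false-positive proportion.

    Each grid point gets a permutation test; the winner minimizes
    ``optimality_score``, ties broken by larger observed count, then by grid
    order.  If no grid point flags any marker on the observed labels, the
    best setting is ``None`` (none-found) and the full table is still
    returned.
    """
    param_grid = param_grid or default_param_grid()
    if not param_grid:
        raise ValueError("param_grid is empty")
    if method not in METHODS:
        raise ValueError("method must be 'I', 'II' or 'III'")

    results: list[PermutationResult] = []
    for i, params in enumerate(param_grid):
        if method == "I":
            scan = lambda m, p=params: scan_method_I(g, m, system, p)
        elif method == "II":
            scan = lambda m, p=params: scan_method_II(g, m, system, p)
        else:
            scan = lambda m, p=params: scan_method_III(
                presence, tags, m, tag_samples, system, p
            )
        results.append(permutation_test(scan, meta, n_permutations, seed=seed + i))

    if all(r.observed_count == 0 for r in results):
        return None, results
    order = sorted(
        range(len(param_grid)),
        key=lambda i: (results[i].optimality_score, -results[i].observed_count, i),
    )
    best = order[0]
    return param_grid[best], results


def radsex_distribution(
    presence: np.ndarray, meta: pd.DataFrame, samples: list[str]
) -> pd.DataFrame:
    """Tag counts over (number of males, number of females) presence cells.

    Returns the complete ``(n_males+1) x (n_females+1)`` contingency surface
    (rows: males present, columns: females present), the layout of a RadSex
    distribution table.
    """
    male, female = _sex_masks(meta, samples)
    n_m_present = presence[:, male].sum(axis=1)
    n_f_present = presence[:, female].sum(axis=1)
    n_m, n_f = int(male.sum()), int(female.sum())
    surface = np.zeros((n_m + 1, n_f + 1), dtype=int)
    np.add.at(surface, (n_m_present, n_f_present), 1)
    return pd.DataFrame(
        surface,
        index=pd.Index(range(n_m + 1), name="n_males_present"),
        columns=pd.Index(range(n_f + 1), name="n_females_present"),
    )


def yates_chi2(table: np.ndarray) -> tuple[float, float]:
    """Yates-corrected chi-squared (1 df) for a 2x2 table via scipy."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def radsex_test(
    presence: np.ndarray,
    meta: pd.DataFrame,
    samples: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-tag sex association: Yates chi-squared with Bonferroni correction.

    Each tag yields a 2x2 (present/absent x male/female) table.  The
    Bonferroni denominator is the number of *testable* tags — those present
    in at least one and at most N-1 samples; degenerate tags get chi2 = 0,
    p = 1 and never reach significance.  ``significant`` means
    ``p_bonferroni < alpha``.
    """
    male, female = _sex_masks(meta, samples)
    if male.sum() == 0 or female.sum() == 0:
        raise ValueError("need at least one sample of each sex")
    n_m, n_f = int(male.sum()), int(female.sum())
    m_pres = presence[:, male].sum(axis=1)
    f_pres = presence[:, female].sum(axis=1)
    total_pres = m_pres + f_pres
    n_sexed = n_m + n_f
    testable = (total_pres >= 1) & (total_pres <= n_sexed - 1)
    n_tests = int(testable.sum())

    chi2s = np.zeros(len(presence))
    p_raw = np.ones(len(presence))
    for i in np.flatnonzero(testable):
        tab = np.array(
            [
                [m_pres[i], f_pres[i]],
                [n_m - m_pres[i], n_f - f_pres[i]],
            ]
        )
        chi2s[i], p_raw[i] = yates_chi2(tab)
    p_bonf = np.minimum(p_raw * max(n_tests, 1), 1.0)
    df = pd.DataFrame(
        {
            "n_males_present": m_pres,
            "n_females_present": f_pres,
            "chi2_yates": chi2s,
            "p_raw": p_raw,
            "p_bonferroni": p_bonf,
            "testable": testable,
            "significant": testable & (p_bonf < alpha),
        }
    )
    df.attrs["n_tests"] = n_tests
    return df
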