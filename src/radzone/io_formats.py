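"""Readers, writers and genotype-quality filters for the tabular formats the
pipeline touches.

Genotypes are stored as alternate-allele dosage (0, 1, 2; NaN = missing);
phase is ignored throughout, as every downstream statistic is phase-free.
The canonical interchange dialect is TSV (tab-separated, ``NA`` or ``.`` for
missing, header row of sample ids); VCF support is read-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("radzone")

SEXES = ("M", "F", "unknown")
MITOTYPES = ("A", "B", "unknown")

#: metadata columns required of every sample table
META_COLUMNS = ["sample_id", "sex", "population_id", "distance_km", "mitotype"]


@dataclass
class SampleMeta:
    """One sample's metadata row.

    ``distance_km`` is the 1-D position along the transect, 0 at the
    northeastern (B. bufo) end and increasing southwestward; it must be
    identical for all samples of one population.
    """

    sample_id: str
    sex: str = "unknown"
    population_id: str = ""
    distance_km: float = 0.0
    mitotype: str = "unknown"
    species_label: str | None = None


def make_meta(records: list[SampleMeta] | pd.DataFrame) -> pd.DataFrame:
    """Build and validate the canonical sample-metadata table."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([vars(r) for r in records])
    if "species_label" not in df.columns:
        df["species_label"] = None
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"invalid sex codes: {sorted(bad_sex)}")
    bad_mito = set(df["mitotype"]) - set(MITOTYPES)
    if bad_mito:
        raise ValueError(f"invalid mitotype codes: {sorted(bad_mito)}")
    if (df["distance_km"].astype(float) < 0).any():
        raise ValueError("distance_km must be >= 0")
    # one position per population
    span = df.groupby("population_id")["distance_km"].nunique()
    if (span > 1).any():
        raise ValueError(
            f"populations with inconsistent distance_km: {span[span > 1].index.tolist()}"
        )
    return df.reset_index(drop=True)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population_id": str})
    return make_meta(df)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LocusInfo:
    """Identity of one SNP: the RAD tag it sits on and its offset there."""

    locus_id: str
    tag_id: str
    snp_index_in_tag: int = 0
    ref_allele: str = "A"
    alt_allele: str = "T"


@dataclass
class GenotypeMatrix:
    """Loci x samples diploid dosage matrix.

    ``dosage[l, n]`` counts the designated alternate allele (0, 1 or 2);
    missing calls are NaN.  ``depth`` (same shape) is optional per-genotype
    read depth, used only by the coverage filter.
    """

    loci: list[LocusInfo]
    samples: list[str]
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.loci)}, {len(self.samples)})"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape mismatch")
        seen = set()
        for li in self.loci:
            key = (li.tag_id, li.snp_index_in_tag)
            if key in seen:
                raise ValueError(f"duplicate (tag_id, snp_index_in_tag): {key}")
            seen.add(key)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def locus_ids(self) -> list[str]:
        return [li.locus_id for li in self.loci]

    def missingness(self) -> np.ndarray:
        """Per-locus fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=1)

    def heterozygosity(self) -> np.ndarray:
        """Per-locus heterozygote fraction among non-missing calls."""
        called = ~np.isnan(self.dosage)
        n = called.sum(axis=1)
        het = np.nansum(self.dosage == 1.0, axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, het / np.maximum(n, 1), np.nan)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            loci=[self.loci[i] for i in idx],
            samples=list(self.samples),
            dosage=self.dosage[idx],
            depth=None if self.depth is None else self.depth[idx],
        )

    def sample_columns(self, sample_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.locus_ids, columns=self.samples)


@dataclass
class TagMatrix:
    """Unique RAD tag x sample read-depth counts."""

    tags: list[str]
    samples: list[str]
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=int)
        if self.depth.shape != (len(self.tags), len(self.samples)):
            raise ValueError("depth shape mismatch")
        if (self.depth < 0).any():
            raise ValueError("tag depths must be >= 0")
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("tag sequences must be unique")


@dataclass
class FilterParams:
    """Genotype-quality filters applied after SNP calling.

    Defaults mirror standard RADseq practice: minimum per-genotype coverage 8
    reads, loci called in at least 80% of individuals of each group (both
    sexes), and whole-dataset heterozygosity at most 75% to drop over-merged
    paralogs.
    """

    min_locus_coverage: int = 8
    min_call_rate_per_group: float = 0.8
    n_groups_required: int = 2
    max_locus_heterozygosity: float = 0.75

    def __post_init__(self):
        if self.min_locus_coverage < 1:
            raise ValueError("min_locus_coverage must be >= 1")
        if not 0 < self.min_call_rate_per_group <= 1:
            raise ValueError("min_call_rate_per_group must be in (0, 1]")
        if not 0 < self.max_locus_heterozygosity <= 1:
            raise ValueError("max_locus_heterozygosity must be in (0, 1]")
        if self.n_groups_required < 1:
            raise ValueError("n_groups_required must be >= 1")


MISSING_TOKENS = {"NA", ".", "", "nan", "NaN"}


def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv`` or ``vcf``.

    The TSV dialect has a header row ``locus_id<TAB>tag_id<TAB>snp_index_in_tag
    <TAB>ref<TAB>alt<TAB><sample...>`` and one locus per row with 0/1/2/NA
    dosage entries.  VCF records must be diploid; dosage is the alternate
    allele count, ``./.`` is missing.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["locus_id", "tag_id", "snp_index_in_tag", "ref", "alt"]:
            raise ValueError(
                f"{path}: line 1: expected header starting with "
                "locus_id, tag_id, snp_index_in_tag, ref, alt"
            )
        samples = header[5:]
        loci: list[LocusInfo] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + len(samples):
                raise ValueError(
                    f"{path}: line {lineno}: expected {5 + len(samples)} fields, "
                    f"got {len(parts)}"
                )
            loci.append(
                LocusInfo(
                    locus_id=parts[0],
                    tag_id=parts[1],
                    snp_index_in_tag=int(parts[2]),
                    ref_allele=parts[3],
                    alt_allele=parts[4],
                )
            )
            row = []
            for tok in parts[5:]:
                if tok in MISSING_TOKENS:
                    row.append(np.nan)
                elif tok in ("0", "1", "2"):
                    row.append(float(tok))
                else:
                    raise ValueError(
                        f"{path}: line {lineno}: invalid dosage entry {tok!r}"
                    )
            rows.append(row)
    dosage = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(loci=loci, samples=samples, dosage=dosage)


def _read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[LocusInfo] = []
    rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    have_depth = False
    for var in vcf:
        gts = var.genotype.array()
        if gts.shape[1] - 1 != 2:  # last column is the phase flag
            raise ValueError(f"non-diploid genotype at {var.CHROM}:{var.POS}")
        alleles = gts[:, :2]
        row = np.where((alleles < 0).any(axis=1), np.nan, (alleles > 0).sum(axis=1))
        rows.append(row.astype(float))
        tag = str(var.CHROM)
        loci.append(
            LocusInfo(
                locus_id=var.ID if var.ID not in (None, ".") else f"{tag}:{var.POS}",
                tag_id=tag,
                snp_index_in_tag=int(var.POS),
                ref_allele=var.REF,
                alt_allele=var.ALT[0] if var.ALT else ".",
            )
        )
        dp = var.format("DP")
        if dp is not None:
            have_depth = True
            depth_rows.append(np.asarray(dp).reshape(-1))
        else:
            depth_rows.append(np.zeros(len(samples), dtype=int))
    dosage = np.array(rows) if rows else np.empty((0, len(samples)))
    depth = np.array(depth_rows) if have_depth else None
    return GenotypeMatrix(loci=loci, samples=samples, dosage=dosage, depth=depth)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write the TSV genotype dialect (round-trips with :func:`read_genotypes`)."""
    with open(path, "w") as fh:
        fh.write(
            "\t".join(["locus_id", "tag_id", "snp_index_in_tag", "ref", "alt"] + list(g.samples))
            + "\n"
        )
        for li, row in zip(g.loci, g.dosage):
            toks = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(
                "\t".join(
                    [li.locus_id, li.tag_id, str(li.snp_index_in_tag), li.ref_allele, li.alt_allele]
                    + toks
                )
                + "\n"
            )


def read_tag_matrix(path) -> TagMatrix:
    """Read a RadSex-process-style tag-depth table: ``tag<TAB><sample...>``."""
    df = pd.read_csv(path, sep="\t", dtype={"tag": str})
    if "tag" not in df.columns:
        raise ValueError(f"{path}: expected a 'tag' column")
    samples = [c for c in df.columns if c != "tag"]
    return TagMatrix(
        tags=df["tag"].tolist(),
        samples=samples,
        depth=df[samples].to_numpy(dtype=int),
    )


def write_tag_matrix(t: TagMatrix, path) -> None:
    df = pd.DataFrame(t.depth, columns=t.samples)
    df.insert(0, "tag", t.tags)
    df.to_csv(path, sep="\t", index=False)


def apply_locus_filters(
    g: GenotypeMatrix,
    meta: pd.DataFrame,
    params: FilterParams | None = None,
    group_by: str = "sex",
) -> GenotypeMatrix:
    """Apply call-rate, heterozygosity and (when depth is known) coverage filters.

    A locus is retained iff its call rate is at least
    ``min_call_rate_per_group`` in every group (sexes or populations, unknown
    sex excluded) and its whole-dataset heterozygote fraction does not exceed
    ``max_locus_heterozygosity``.  Genotypes below ``min_locus_coverage`` reads
    are set missing first — but only when per-genotype depth is present;
    otherwise the coverage filter is skipped with a logged notice.
    """
    params = params or FilterParams()
    if group_by not in ("sex", "population"):
        raise ValueError("group_by must be 'sex' or 'population'")
    meta = meta.set_index("sample_id").loc[g.samples].reset_index()
    key = "sex" if group_by == "sex" else "population_id"
    labels = meta[key].to_numpy()
    if group_by == "sex":
        groups = [s for s in ("M", "F") if (labels == s).any()]
    else:
        groups = sorted(set(labels))
    if len(groups) < params.n_groups_required:
        raise ValueError(
            f"need >= {params.n_groups_required} non-empty groups, got {groups}"
        )

    dosage = g.dosage.copy()
    if g.depth is not None:
        dosage[g.depth < params.min_locus_coverage] = np.nan
    else:
        logger.info(
            "no per-genotype depth available: coverage filter (min %d reads) skipped",
            params.min_locus_coverage,
        )

    called = ~np.isnan(dosage)
    keep = np.ones(g.n_loci, dtype=bool)
    for grp in groups:
        cols = labels == grp
        if cols.sum() == 0:
            raise ValueError(f"empty group {grp!r}")
        rate = called[:, cols].mean(axis=1)
        keep &= rate >= params.min_call_rate_per_group

    n_called = called.sum(axis=1)
    n_het = np.nansum(dosage == 1.0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    keep &= het <= params.max_locus_heterozygosity
    keep &= n_called > 0

    if not keep.any():
        logger.warning("no locus survived filtering")
    out = GenotypeMatrix(
        loci=[g.loci[i] for i in np.flatnonzero(keep)],
        samples=list(g.samples),
        dosage=dosage[keep],
        depth=None if g.depth is None else g.depth[keep],
    )
    return out


def tag_presence(t: TagMatrix, min_cov: int = 5) -> np.ndarray:
    """Boolean presence matrix: a tag is present in a sample iff its depth is
    at least ``min_cov`` reads (default 5)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    return t.depth >= min_cov


FREQ_COLUMNS = ["population_id", "distance_km", "n_alleles", "focal_allele_count"]


def make_frequency_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a population allele-frequency table and sort it by distance."""
    missing = [c for c in FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frequency table missing columns: {missing}")
    df = df.copy()
    df["n_alleles"] = df["n_alleles"].astype(int)
    df["focal_allele_count"] = df["focal_allele_count"].astype(int)
    if (df["n_alleles"] <= 0).any():
        raise ValueError("n_alleles must be positive")
    bad = (df["focal_allele_count"] < 0) | (df["focal_allele_count"] > df["n_alleles"])
    if bad.any():
        rows = df.loc[bad, "population_id"].tolist()
        raise ValueError(f"focal_allele_count out of [0, n_alleles] for: {rows}")
    return df.sort_values("distance_km", kind="stable").reset_index(drop=True)


def read_frequency_table(path) -> pd.DataFrame:
    return make_frequency_table(pd.read_csv(path, sep="\t", dtype={"population_id": str}))


def write_frequency_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
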