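"""End-to-end pipeline orchestration: simulate -> scan -> zone statistics ->
clines, driven by a flat sectioned key-value config, with a JSON run
manifest for reproducibility.

The config format is INI-style::

    [run]
    stages = simulate-zone, zone-stats, fit-cline
    outdir = out
    seed = 1

    [simulate-zone]
    n_ind_per_pop = 10
    ...

Every output file is listed in ``manifest.json`` with its SHA-256 hash, the
seed and the package version; rerunning an identical config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd

from . import __version__
from . import clinefit, io_formats, sexscan, synthdata, zonestats

logger = logging.getLogger("radzone")

KNOWN_STAGES = (
    "simulate-sexlink",
    "simulate-zone",
    "scan-sex",
    "radsex-test",
    "call-diagnostics",
    "zone-stats",
    "fit-cline",
    "fit-loci",
    "tail-test",
)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    stages: list[str] = field(default_factory=list)
    seed: int = 0
    log_level: str = "INFO"
    sections: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown} (known: {KNOWN_STAGES})")
        for sect in self.sections.values():
            for key in ("genotypes", "meta", "tags", "frequencies"):
                if key in sect and not Path(sect[key]).exists():
                    raise FileNotFoundError(f"input path does not exist: {sect[key]}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        run = dict(cp["run"]) if cp.has_section("run") else {}
        stages = [s.strip() for s in run.get("stages", "").split(",") if s.strip()]
        sections = {name: dict(cp[name]) for name in cp.sections() if name != "run"}
        return cls(
            outdir=Path(run.get("outdir", "radzone_out")),
            stages=stages,
            seed=int(run.get("seed", 0)),
            log_level=run.get("log_level", "INFO"),
            sections=sections,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _coerce_config(section: dict[str, str], cls):
    """Build a dataclass config from string key-values, casting by field type."""
    kwargs = {}
    for f in dc_fields(cls):
        if f.name not in section:
            continue
        raw = section[f.name]
        if f.type in ("int", int):
            kwargs[f.name] = int(raw)
        elif f.type in ("float", float):
            kwargs[f.name] = float(raw)
        elif f.name in ("pop_positions_km", "autosomal_maf_range"):
            kwargs[f.name] = tuple(float(v) for v in raw.split(","))
        else:
            kwargs[f.name] = raw
    return cls(**kwargs)


def _cline_model_to_dict(m: clinefit.ClineModel) -> dict:
    return {
        "c": m.c, "w": m.w, "tail_config": m.tail_config,
        "delta_L": m.delta_L, "delta_R": m.delta_R,
        "tau_L": m.tau_L, "tau_R": m.tau_R,
        "p_min": m.p_min, "p_max": m.p_max,
    }


def _fit_to_dict(f: clinefit.ClineFit) -> dict:
    return {
        "model": _cline_model_to_dict(f.model),
        "logL": f.logL,
        "aic": f.aic,
        "ci": {k: list(v) for k, v in f.ci.items()},
        "n_pops": f.n_pops,
        "converged": f.converged,
        "hit_bounds": f.hit_bounds,
    }


class _Context:
    """In-memory hand-off between stages plus file registration."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.outputs: list[Path] = []
        self.genotypes = None
        self.meta = None
        self.tags = None
        self.freq_tables = None
        self.panel = None
        self.locus_fits = None

    def emit(self, path: Path):
        self.outputs.append(path)

    def section(self, name: str) -> dict[str, str]:
        return self.cfg.sections.get(name, {})

    def need_genotypes(self, sect):
        if "genotypes" in sect:
            self.genotypes = io_formats.read_genotypes(
                sect["genotypes"], sect.get("format", "tsv")
            )
        if "meta" in sect:
            self.meta = io_formats.read_metadata(sect["meta"])
        if self.genotypes is None or self.meta is None:
            raise ValueError("stage needs genotypes + metadata (from config or a prior stage)")


def _stage_simulate_sexlink(ctx: _Context):
    sect = dict(ctx.section("simulate-sexlink"))
    sect.setdefault("seed", str(ctx.cfg.seed))
    config = _coerce_config(sect, synthdata.SexLinkSimConfig)
    g, t, meta, truth = synthdata.simulate_sexlinked(config)
    ctx.genotypes, ctx.tags, ctx.meta = g, t, meta
    out = ctx.cfg.outdir
    io_formats.write_genotypes(g, out / "sexlink_genotypes.tsv")
    io_formats.write_tag_matrix(t, out / "sexlink_tags.tsv")
    io_formats.write_metadata(meta, out / "sexlink_meta.tsv")
    _json_dump(truth, out / "sexlink_truth.json")
    for name in ("sexlink_genotypes.tsv", "sexlink_tags.tsv", "sexlink_meta.tsv",
                 "sexlink_truth.json"):
        ctx.emit(out / name)


def _stage_simulate_zone(ctx: _Context):
    sect = dict(ctx.section("simulate-zone"))
    sect.setdefault("seed", str(ctx.cfg.seed))
    config = _coerce_config(sect, synthdata.ZoneSimConfig)
    g, meta, freq_tables, truth = synthdata.simulate_zone(config)
    ctx.genotypes, ctx.meta, ctx.freq_tables = g, meta, freq_tables
    out = ctx.cfg.outdir
    io_formats.write_genotypes(g, out / "zone_genotypes.tsv")
    io_formats.write_metadata(meta, out / "zone_meta.tsv")
    long = pd.concat(
        [tab.assign(locus_id=lid) for lid, tab in freq_tables.items()],
        ignore_index=True,
    )
    long.to_csv(out / "zone_frequencies.tsv", sep="\t", index=False)
    _json_dump(
        {
            "shared_cline": _cline_model_to_dict(truth["shared_cline"]),
            "mtdna_cline": _cline_model_to_dict(truth["mtdna_cline"]),
            "locus_clines": {
                lid: _cline_model_to_dict(m) for lid, m in truth["locus_clines"].items()
            },
        },
        out / "zone_truth.json",
    )
    for name in ("zone_genotypes.tsv", "zone_meta.tsv", "zone_frequencies.tsv",
                 "zone_truth.json"):
        ctx.emit(out / name)


def _stage_scan_sex(ctx: _Context):
    sect = ctx.section("scan-sex")
    ctx.need_genotypes(sect)
    params = sexscan.ScanParams(
        het_freq_tol=float(sect.get("het_freq_tol", 0.05)),
        hom_freq_max=float(sect.get("hom_freq_max", 0.05)),
        het_het_min=float(sect.get("het_het_min", 0.9)),
        hom_het_max=float(sect.get("hom_het_max", 0.05)),
        specificity_min=float(sect.get("specificity_min", 0.9)),
    )
    n_perm = int(sect.get("permutations", 100))
    systems = [s.strip() for s in sect.get("system", "XY,ZW").split(",")]
    result = sexscan.scan_all(ctx.genotypes, ctx.meta, params, systems=systems)
    report = {"counts": result.counts, "candidates": result.candidates, "permutation": {}}
    for system in systems:
        for method, scan_fn in (
            ("I", lambda m, s=system: sexscan.scan_method_I(ctx.genotypes, m, s, params)),
            ("II", lambda m, s=system: sexscan.scan_method_II(ctx.genotypes, m, s, params)),
        ):
            pr = sexscan.permutation_test(scan_fn, ctx.meta, n_perm, seed=ctx.cfg.seed)
            report["permutation"][f"{system}_{method}"] = {
                "observed_count": pr.observed_count,
                "p_value": pr.p_value,
                "percentile95": pr.percentile95,
                "optimality_score": pr.optimality_score,
                "significant": pr.significant,
            }
    out = ctx.cfg.outdir
    _json_dump(report, out / "scan_report.json")
    rows = [
        {"system": sys_, "method": m, "marker_id": mid}
        for sys_, by_m in result.candidates.items()
        for m, ids in by_m.items()
        for mid in ids
    ]
    pd.DataFrame(rows, columns=["system", "method", "marker_id"]).to_csv(
        out / "scan_candidates.tsv", sep="\t", index=False
    )
    ctx.emit(out / "scan_report.json")
    ctx.emit(out / "scan_candidates.tsv")


def _stage_radsex_test(ctx: _Context):
    sect = ctx.section("radsex-test")
    if "tags" in sect:
        ctx.tags = io_formats.read_tag_matrix(sect["tags"])
    if "meta" in sect:
        ctx.meta = io_formats.read_metadata(sect["meta"])
    if ctx.tags is None or ctx.meta is None:
        raise ValueError("radsex-test needs a tag matrix + metadata")
    min_cov = int(sect.get("min_cov", 5))
    presence = io_formats.tag_presence(ctx.tags, min_cov)
    dist = sexscan.radsex_distribution(presence, ctx.meta, ctx.tags.samples)
    test = sexscan.radsex_test(presence, ctx.meta, ctx.tags.samples,
                               alpha=float(sect.get("alpha", 0.05)))
    test.insert(0, "tag", ctx.tags.tags)
    out = ctx.cfg.outdir
    dist.to_csv(out / "radsex_distribution.tsv", sep="\t")
    test.to_csv(out / "radsex_test.tsv", sep="\t", index=False)
    ctx.emit(out / "radsex_distribution.tsv")
    ctx.emit(out / "radsex_test.tsv")


def _stage_call_diagnostics(ctx: _Context):
    sect = ctx.section("call-diagnostics")
    ctx.need_genotypes(sect)
    edge_a = [s.strip() for s in sect.get("edge_pops_a", "").split(",") if s.strip()]
    edge_b = [s.strip() for s in sect.get("edge_pops_b", "").split(",") if s.strip()]
    if not edge_a or not edge_b:
        raise ValueError("call-diagnostics needs edge_pops_a and edge_pops_b")
    panel = zonestats.call_diagnostic_snps(
        ctx.genotypes, ctx.meta, edge_a, edge_b,
        max_missing_in_edges=float(sect.get("max_missing_in_edges", 0.1)),
    )
    ctx.panel = panel
    out = ctx.cfg.outdir
    _json_dump(
        {
            "loci": panel.loci,
            "polarity": panel.polarity,
            "edge_pops_A": panel.edge_pops_A,
            "edge_pops_B": panel.edge_pops_B,
        },
        out / "diagnostic_panel.json",
    )
    ctx.emit(out / "diagnostic_panel.json")


def _stage_zone_stats(ctx: _Context):
    sect = ctx.section("zone-stats")
    ctx.need_genotypes(sect)
    if ctx.panel is None:
        raise ValueError("zone-stats needs the call-diagnostics stage first")
    adm = zonestats.admixture_table(ctx.genotypes, ctx.panel, ctx.meta)
    pops = zonestats.population_summaries(ctx.genotypes, ctx.panel, ctx.meta)
    out = ctx.cfg.outdir
    adm.to_csv(out / "individual_admixture.tsv", sep="\t", index=False)
    pops.to_csv(out / "population_summaries.tsv", sep="\t", index=False)
    ctx.emit(out / "individual_admixture.tsv")
    ctx.emit(out / "population_summaries.tsv")


def _frequency_input(ctx: _Context, sect) -> dict[str, pd.DataFrame]:
    if "frequencies" in sect:
        long = pd.read_csv(sect["frequencies"], sep="\t",
                           dtype={"population_id": str, "locus_id": str})
        if "locus_id" in long.columns:
            return {
                lid: io_formats.make_frequency_table(grp.drop(columns="locus_id"))
                for lid, grp in long.groupby("locus_id", sort=True)
            }
        return {"marker": io_formats.make_frequency_table(long)}
    if ctx.freq_tables is not None:
        return ctx.freq_tables
    raise ValueError("cline stages need a frequency table (config or simulate-zone)")


def _stage_fit_cline(ctx: _Context):
    sect = ctx.section("fit-cline")
    tables = _frequency_input(ctx, sect)
    marker = sect.get("marker", next(iter(tables)))
    tab = tables[marker]
    tails = sect.get("tails", "select")
    n_starts = int(sect.get("n_starts", 20))
    if tails == "select":
        best, table = clinefit.model_select(
            tab, n_starts=n_starts, seed=ctx.cfg.seed, compute_ci=True
        )
        payload = {
            "best": _fit_to_dict(best),
            "by_config": {c: _fit_to_dict(f) for c, f in table.items()},
        }
    else:
        fit = clinefit.fit_cline(tab, tails, n_starts=n_starts, seed=ctx.cfg.seed)
        payload = {"best": _fit_to_dict(fit)}
    payload["marker"] = marker
    out = ctx.cfg.outdir
    _json_dump(payload, out / "cline_fit.json")
    ctx.emit(out / "cline_fit.json")


def _stage_fit_loci(ctx: _Context):
    sect = ctx.section("fit-loci")
    tables = _frequency_input(ctx, sect)
    fits, summary = clinefit.fit_all_loci(
        tables,
        tail_config=sect.get("tails", "both"),
        n_starts=int(sect.get("n_starts", 6)),
        seed=ctx.cfg.seed,
    )
    ctx.locus_fits = fits
    rows = []
    for lid, f in fits.items():
        rows.append(
            {
                "locus_id": lid,
                "model": f.model.tail_config,
                "logL": f.logL,
                "aic": f.aic,
                "c": f.model.c,
                "w": f.model.w,
                "delta_L": f.model.delta_L,
                "tau_L": f.model.tau_L,
                "delta_R": f.model.delta_R,
                "tau_R": f.model.tau_R,
                "converged": f.converged,
            }
        )
    out = ctx.cfg.outdir
    pd.DataFrame(rows).to_csv(out / "locus_clines.tsv", sep="\t", index=False)
    summary.to_csv(out / "locus_cline_summary.tsv", sep="\t", index=False)
    ctx.emit(out / "locus_clines.tsv")
    ctx.emit(out / "locus_cline_summary.tsv")


def _stage_tail_test(ctx: _Context):
    if ctx.locus_fits is None:
        raise ValueError("tail-test needs the fit-loci stage first")
    res = clinefit.tail_asymmetry_test(ctx.locus_fits)
    out = ctx.cfg.outdir
    _json_dump(res, out / "tail_asymmetry.json")
    ctx.emit(out / "tail_asymmetry.json")


_STAGE_FUNCS = {
    "simulate-sexlink": _stage_simulate_sexlink,
    "simulate-zone": _stage_simulate_zone,
    "scan-sex": _stage_scan_sex,
    "radsex-test": _stage_radsex_test,
    "call-diagnostics": _stage_call_diagnostics,
    "zone-stats": _stage_zone_stats,
    "fit-cline": _stage_fit_cline,
    "fit-loci": _stage_fit_loci,
    "tail-test": _stage_tail_test,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write ``manifest.json``.

    The manifest lists every output file with its SHA-256 hash, the seed,
    the package version and the effective config; a stage failure is
    recorded (stage name + error) and aborts subsequent stages.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.outdir.mkdir(parents=True, exist_ok=True)
    ctx = _Context(config)
    completed, failure = [], None
    for stage in config.stages:
        try:
            _STAGE_FUNCS[stage](ctx)
            completed.append(stage)
        except Exception as e:  # record partial completion
            failure = {"stage": stage, "error": f"{type(e).__name__}: {e}"}
            logger.error("stage %s failed: %s", stage, e)
            break
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages_requested": list(config.stages),
        "stages_completed": completed,
        "failure": failure,
        "config": {
            "run": {"outdir": str(config.outdir), "seed": config.seed,
                    "log_level": config.log_level},
            **config.sections,
        },
        "outputs": {
            str(p.relative_to(config.outdir)): _sha256(p) for p in ctx.outputs
        },
    }
    _json_dump(manifest, config.outdir / "manifest.json")
    return manifest
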