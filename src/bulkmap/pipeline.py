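"""End-to-end orchestration: VCF -> filters -> scans -> candidate regions.

``run_all`` drives the full analysis for one trait group: read (or
simulate) the 4-sample VCF, run the filter chain, compute the ED^5 and
ΔSNP-index tracks for SNP and InDel markers separately, call per-track
regions, intersect the configured track list, apply exclusions, count
genes if an annotation is given, and write every intermediate artifact as
plain text. Also provides the per-chromosome track plot (raw scatter,
fitted line, threshold/bounds, shaded called regions).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import ed as edmod
from . import snpindex as simod
from .filters import FilterConfig, apply_filters
from .regions import Region, count_genes, exclude, intersect_tracks, \
    read_gff3, region_report, total_size_mb, write_bed
from .vario import VariantTable, read_vcf, write_tsv

log = logging.getLogger("bulkmap")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from a single YAML."""

    vcf: str
    outdir: str
    annotation: str | None = None
    trait: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    # ED settings
    bandwidth_bp: float = 2_000_000.0
    power: int = 5
    grid: int = 10_000
    # index settings
    window_bp: int = 2_000_000
    step_bp: int = 10_000
    confidence: float = 0.99
    generation: str = "F3"
    n_individuals: int = 299
    pool_size: int = 30
    # region recipe: tracks to intersect, chromosomes to drop afterwards
    tracks: tuple[str, ...] = ("ED:SNP", "ED:InDel", "INDEX:SNP", "INDEX:InDel")
    drop_chroms: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        filt = FilterConfig(**raw.pop("filters", {}))
        for key in ("tracks", "drop_chroms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(filters=filt, **raw)


def _track_regions(table: VariantTable, cfg: RunConfig,
                   bounds: simod.NullBounds) -> dict[str, list[Region]]:
    """One region set per configured track name (e.g. ``"ED:SNP"``)."""
    out: dict[str, list[Region]] = {}
    tracks: dict[str, object] = {}
    for name in cfg.tracks:
        algo, kind = name.split(":")
        if algo == "ED":
            track = edmod.ed_track(table, marker_kind=kind, power=cfg.power,
                                   bandwidth_bp=cfg.bandwidth_bp)
            out[name] = edmod.call_regions(track, grid=cfg.grid, trait=cfg.trait)
        elif algo == "INDEX":
            sites = simod.index_sites(table, marker_kind=kind)
            track = simod.window_track(sites, window_bp=cfg.window_bp,
                                       step_bp=cfg.step_bp, marker_kind=kind)
            out[name] = simod.call_regions_ci(track, bounds, grid=cfg.grid,
                                              trait=cfg.trait)
        else:
            raise ValueError(f"unknown track {name!r}")
        tracks[name] = track
    _track_regions.last_tracks = tracks  # exposed for plotting/reporting
    return out


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns (and writes) the run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in asdict(cfg).items()},
                    "seed": cfg.seed}
    stage = "read_vcf"
    try:
        table = read_vcf(cfg.vcf)
        report["n_input_variants"] = len(table)

        stage = "filter"
        table, counts = apply_filters(table, cfg.filters)
        report["filter_counts"] = counts
        write_tsv(table, outdir / "filtered.tsv")

        stage = "null_bounds"
        bounds = simod.null_bounds(n_individuals=cfg.n_individuals,
                                   pool_size=cfg.pool_size,
                                   generation=cfg.generation,
                                   confidence=cfg.confidence, seed=cfg.seed)

        stage = "tracks"
        per_track = _track_regions(table, cfg, bounds)
        report["thresholds"] = {}
        for name, track in _track_regions.last_tracks.items():
            if getattr(track, "threshold", None) is not None:
                report["thresholds"][name] = track.threshold
            write_bed(per_track[name], outdir / f"{name.replace(':', '_')}.bed")
        report["per_track_mb"] = {k: round(total_size_mb(v), 4)
                                  for k, v in per_track.items()}

        stage = "intersect"
        sets = [per_track[name] for name in cfg.tracks]
        final = intersect_tracks(sets) if len(sets) >= 2 else list(sets[0])

        stage = "exclude"
        if cfg.drop_chroms:
            final = exclude(final, drop_chroms=cfg.drop_chroms)

        stage = "genes"
        if cfg.annotation:
            final = count_genes(final, read_gff3(cfg.annotation))

        region_report(final).to_csv(outdir / "final_regions.tsv", sep="\t",
                                    index=False)
        write_bed(final, outdir / "final_regions.bed")
        report["final_regions"] = [
            dict(chrom=r.chrom, start=r.start, end=r.end,
                 size_mb=round(r.size_mb, 2), gene_count=r.gene_count)
            for r in final
        ]
        report["final_total_mb"] = round(total_size_mb(final), 4)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    log.info("pipeline complete: %d final regions, %.2f Mb",
             len(report["final_regions"]), report["final_total_mb"])
    return report


def plot_tracks(track, out: str | Path, regions: list[Region] | None = None) -> None:
    """Per-chromosome association panels: raw scatter, fitted line,
    threshold or CI bounds, shaded called regions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(set(track.chroms.tolist()))
    if not chroms:
        fig, ax = plt.subplots(figsize=(6, 2))
        ax.text(0.5, 0.5, "empty track", ha="center", va="center")
        ax.set_axis_off()
        import warnings
        warnings.warn("empty track: placeholder panel written")
        fig.savefig(out, dpi=100)
        plt.close(fig)
        return
    fig, axes = plt.subplots(1, len(chroms), figsize=(3.2 * len(chroms), 2.8),
                             sharey=True, squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        sub = track.for_chrom(chrom)
        mb = sub.positions / 1e6
        ax.scatter(mb, sub.raw, s=3, alpha=0.4, linewidths=0)
        ax.plot(mb, sub.fitted, color="black", lw=1.2)
        if sub.threshold is not None:
            ax.axhline(sub.threshold, color="red", ls=":", lw=1)
        if sub.lower is not None:
            ax.plot(mb, sub.lower, color="red", ls=":", lw=1)
            ax.plot(mb, sub.upper, color="red", ls=":", lw=1)
        for r in regions or ():
            if r.chrom == chrom:
                ax.axvspan(r.start / 1e6, r.end / 1e6, color="orange", alpha=0.25)
        ax.set_title(chrom, fontsize=9)
        ax.set_xlabel("Mb", fontsize=8)
    axes[0][0].set_ylabel(track.statistic_kind, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
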