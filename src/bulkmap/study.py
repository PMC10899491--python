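"""The package's reference simulation study, used by tests and examples.

Design: 5 chromosomes x 30 Mb, one parent-divergent marker every 20 kb,
299 F3 individuals, 10% tails pooled (30 per pool), 50X bulks, 31X
parents, 4 cM/Mb. The QTL arm places a single additive locus of a chosen
size in phenotypic SDs at Chr3:15 Mb; the null arm has no QTL and a
pure-noise phenotype.

For an additive locus in an F3 the dosage variance is 3/4, so an effect
of s phenotypic SDs corresponds to a narrow-sense heritability of
h2 = 0.75 * s^2 (0.48 for s = 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ed as edmod
from . import snpindex as simod
from .filters import FilterConfig, apply_filters
from .regions import Region, intersect_tracks, total_size_mb
from .sim import simulate_experiment, study_design

GENOME_MB = 150.0
QTL_CHROM, QTL_POS = "Chr3", 15_000_000


def heritability_for_effect_sd(effect_sd: float) -> float:
    """h2 giving a single F3 QTL an effect of *effect_sd* phenotypic SDs."""
    v = 0.75 * effect_sd**2
    return v / (1.0 + v)


@dataclass
class SeedResult:
    """Outcome of one simulated study seed."""

    ed_regions: list[Region]
    idx_regions: list[Region]
    ed_total_mb: float
    idx_outside_fraction: float  # windows outside the null bounds
    ed_covered: bool
    idx_covered: bool
    midpoint_offset_mb: float | None  # final reported region vs true QTL


def run_seed(seed: int, effect_sd: float | None = 0.8,
             bounds: simod.NullBounds | None = None) -> SeedResult:
    """Simulate one study seed and run both association scans.

    ``effect_sd=None`` runs the null arm. ``bounds`` may be precomputed
    (they depend only on the design) and are otherwise simulated here from
    the same seed.
    """
    if effect_sd is None:
        genome, qtls, cfg = study_design(seed=seed, heritability=0.0,
                                         qtl_effect=None)
    else:
        h2 = heritability_for_effect_sd(effect_sd)
        genome, qtls, cfg = study_design(seed=seed, heritability=h2,
                                         qtl_effect=1.0)
    table, _truth = simulate_experiment(genome, qtls, cfg)
    table, _log = apply_filters(table, FilterConfig(seq_error_rate=cfg.seq_error_rate))

    track = edmod.ed_track(table, marker_kind="SNP")
    ed_regions = edmod.call_regions(track)

    if bounds is None:
        bounds = simod.null_bounds(pool_size=30, generation=cfg.generation,
                                   seed=seed)
    sites = simod.index_sites(table, marker_kind="SNP")
    wtrack = simod.window_track(sites)
    idx_regions = simod.call_regions_ci(wtrack, bounds)
    outside = float(np.mean((wtrack.fitted > wtrack.upper)
                            | (wtrack.fitted < wtrack.lower)))

    ed_cov = any(r.contains(QTL_CHROM, QTL_POS) for r in ed_regions)
    idx_cov = any(r.contains(QTL_CHROM, QTL_POS) for r in idx_regions)
    offset = None
    if ed_cov and idx_cov:
        final = intersect_tracks([ed_regions, idx_regions])
        hit = [r for r in final if r.contains(QTL_CHROM, QTL_POS)]
        if hit:
            offset = abs(hit[0].midpoint - QTL_POS) / 1e6
    return SeedResult(
        ed_regions=ed_regions,
        idx_regions=idx_regions,
        ed_total_mb=total_size_mb(ed_regions),
        idx_outside_fraction=outside,
        ed_covered=ed_cov,
        idx_covered=idx_cov,
        midpoint_offset_mb=offset,
    )


def null_study(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Null-calibration arm: median called-region burden over seeds."""
    bounds = simod.null_bounds(pool_size=30, generation="F3", seed=base_seed)
    results = [run_seed(base_seed + 1000 + i, effect_sd=None, bounds=bounds)
               for i in range(n_seeds)]
    return {
        "ed_called_fraction_pct": 100.0 * float(np.median(
            [r.ed_total_mb / GENOME_MB for r in results])),
        "idx_outside_pct": 100.0 * float(np.median(
            [r.idx_outside_fraction for r in results])),
        "n_seeds": n_seeds,
    }


def recovery_study(n_seeds: int = 20, base_seed: int = 0,
                   effect_sd: float = 0.8) -> dict:
    """QTL-recovery arm: coverage and localisation rates over seeds."""
    bounds = simod.null_bounds(pool_size=30, generation="F3", seed=base_seed)
    results = [run_seed(base_seed + 2000 + i, effect_sd=effect_sd, bounds=bounds)
               for i in range(n_seeds)]
    offsets = [r.midpoint_offset_mb for r in results]
    return {
        "ed_covered": sum(r.ed_covered for r in results),
        "idx_covered": sum(r.idx_covered for r in results),
        "midpoint_within_2mb": sum(1 for o in offsets
                                   if o is not None and o <= 2.0),
        "n_seeds": n_seeds,
    }
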