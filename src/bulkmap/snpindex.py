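"""ΔSNP-index association scan with simulated null confidence bounds.

At each informative site the reads of each bulk are attributed to the two
parents: M counts are reads carrying the female-parent (P1) allele, P
counts the male-parent (P2) allele. The SNP-index of a bulk is
M / (M + P) and

    ΔSNP-index = M_low/(M_low + P_low) - M_high/(M_high + P_high)

which approaches ±1 at loci fully linked to the pooled trait and 0
elsewhere. Significance uses depth-dependent null bounds simulated under
no linkage: pool genotypes are drawn from the generation's segregation
ratios (F2 1/4:1/2:1/4, F3 3/8:1/4:3/8), pooled allele frequencies
formed, and read counts drawn binomially at each depth; the (1-c)/2 and
1-(1-c)/2 quantiles of the null Δ give the bounds at confidence c
(default 0.99). Tracks are window-averaged (2 Mb windows every 10 kb by
default) and windows outside the bounds at their mean depth become
candidate regions. Identical machinery applies to SNPs and InDels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ed import AssociationTrack, _merge_bins
from .regions import Region
from .vario import PooledVariant, VariantTable

SEGREGATION = {
    "F2": (0.25, 0.50, 0.25),
    "F3": (0.375, 0.25, 0.375),
}


@dataclass
class IndexSite:
    """Parental-origin read depths and indices of one site."""

    chrom: str
    pos: int
    m_low: int
    p_low: int
    m_high: int
    p_high: int

    @property
    def index_low(self) -> float | None:
        return snp_index(self.m_low, self.p_low)

    @property
    def index_high(self) -> float | None:
        return snp_index(self.m_high, self.p_high)

    @property
    def delta(self) -> float | None:
        return delta_snp_index(self)

    @property
    def min_depth(self) -> int:
        return min(self.m_low + self.p_low, self.m_high + self.p_high)


def snp_index(m: int, p: int) -> float | None:
    """Fraction of a bulk's reads carrying the female-parent allele.

    Returns ``None`` at zero total depth (site skipped, logged upstream).
    """
    tot = m + p
    if tot == 0:
        return None
    return m / tot


def delta_snp_index(site: IndexSite) -> float | None:
    """index_low - index_high; in [-1, 1], ±1 at fully linked loci."""
    il, ih = site.index_low, site.index_high
    if il is None or ih is None:
        return None
    return il - ih


def index_sites(table: VariantTable, marker_kind: str = "SNP") -> list[IndexSite]:
    """Attribute bulk reads to parental origin for one marker class.

    Requires the parent-consistency filter to have run: both parents
    homozygous for different alleles. The female parent (P1) defines the
    M counts, the male parent (P2) the P counts.
    """
    sites = []
    for r in table.of_kind(marker_kind):
        if r.p1_gt is None or r.p2_gt is None:
            continue
        a1, a2 = r.p1_gt[0], r.p2_gt[0]
        if r.p1_gt[0] != r.p1_gt[1] or r.p2_gt[0] != r.p2_gt[1] or a1 == a2:
            raise ValueError(
                f"non-informative parents at {r.chrom}:{r.pos}; run the "
                "parent-consistency filter first"
            )
        sites.append(IndexSite(r.chrom, r.pos,
                               m_low=r.low_ad[a1], p_low=r.low_ad[a2],
                               m_high=r.high_ad[a1], p_high=r.high_ad[a2]))
    return sites


# ---------------------------------------------------------------------------
# Null bounds

@dataclass
class NullBounds:
    """Depth-indexed (lower, upper) quantiles of Δ under no linkage."""

    depths: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    confidence: float

    def at(self, depth: float) -> tuple[float, float]:
        """Bounds at a depth, linearly interpolated on the grid (clamped)."""
        lo = float(np.interp(depth, self.depths, self.lower))
        hi = float(np.interp(depth, self.depths, self.upper))
        return lo, hi


def null_bounds(depth_grid: np.ndarray | None = None,
                n_individuals: int = 299, pool_size: int = 30,
                generation: str = "F3", confidence: float = 0.99,
                n_sims: int = 10_000, seed: int = 0) -> NullBounds:
    """Simulate the no-linkage distribution of ΔSNP-index per depth.

    Each simulation draws two independent pools of ``pool_size``
    genotypes from the generation's segregation ratios, forms the pooled
    allele frequencies, and draws binomial read counts for both bulks at
    every depth on the grid. Bounds are the symmetric ``confidence``
    quantiles, keyed by the minimum bulk depth.
    """
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    if generation not in SEGREGATION:
        raise ValueError(f"unknown generation {generation!r}")
    if pool_size > n_individuals:
        raise ValueError("pool_size cannot exceed n_individuals")
    if depth_grid is None:
        depth_grid = np.arange(4, 201, 2)
    depth_grid = np.asarray(depth_grid, dtype=int)
    if (depth_grid <= 0).any():
        raise ValueError("depth grid must be positive")
    rng = np.random.default_rng(seed)
    probs = SEGREGATION[generation]
    # pooled female-parent allele frequency per simulated pool; genotype
    # class counts are multinomial, equivalent to per-individual draws but
    # O(1) in pool size
    def pool_freq() -> np.ndarray:
        counts = rng.multinomial(pool_size, probs, size=n_sims)
        return (counts[:, 1] + 2 * counts[:, 2]) / (2.0 * pool_size)

    p_low = pool_freq()
    p_high = pool_freq()
    alpha = (1.0 - confidence) / 2.0
    lower = np.empty(depth_grid.size)
    upper = np.empty(depth_grid.size)
    for i, d in enumerate(depth_grid):
        idx_low = rng.binomial(d, p_low) / d
        idx_high = rng.binomial(d, p_high) / d
        delta = idx_low - idx_high
        lower[i] = np.quantile(delta, alpha)
        upper[i] = np.quantile(delta, 1.0 - alpha)
    return NullBounds(depth_grid.astype(float), lower, upper, confidence)


# ---------------------------------------------------------------------------
# Window track and region calling

def window_track(sites: list[IndexSite], window_bp: int = 2_000_000,
                 step_bp: int = 10_000, marker_kind: str = "SNP") -> AssociationTrack:
    """Sliding-window mean of Δ along each chromosome.

    Window centers sit on the ``step_bp`` grid from the first to the last
    site of the chromosome; each window averages the Δ of sites within
    ±window/2. Empty windows are absent (dropped), not zero. The track
    also carries each window's mean minimum-bulk-depth for CI lookup.
    """
    usable = [s for s in sites if s.delta is not None]
    chroms_out: list[str] = []
    centers_out: list[int] = []
    raw_out: list[float] = []
    depth_out: list[float] = []
    for chrom in sorted({s.chrom for s in usable}):
        group = sorted((s for s in usable if s.chrom == chrom), key=lambda s: s.pos)
        pos = np.array([s.pos for s in group], dtype=float)
        delta = np.array([s.delta for s in group])
        depth = np.array([s.min_depth for s in group], dtype=float)
        half = window_bp / 2.0
        first = int(pos[0] // step_bp) * step_bp
        last = int(pos[-1] // step_bp) * step_bp
        for c in range(first, last + step_bp, step_bp):
            lo = np.searchsorted(pos, c - half, side="left")
            hi = np.searchsorted(pos, c + half, side="right")
            if hi <= lo:
                continue
            chroms_out.append(chrom)
            centers_out.append(c)
            raw_out.append(float(delta[lo:hi].mean()))
            depth_out.append(float(depth[lo:hi].mean()))
    raw = np.array(raw_out)
    return AssociationTrack(
        chroms=np.array(chroms_out), positions=np.array(centers_out, dtype=np.int64),
        raw=raw, fitted=raw.copy(), statistic_kind="DELTA_INDEX",
        marker_kind=marker_kind, window_depth=np.array(depth_out),
    )


def attach_bounds(track: AssociationTrack, bounds: NullBounds) -> AssociationTrack:
    """Interpolate the null bounds onto each window's mean depth."""
    if track.window_depth is None:
        raise ValueError("track carries no window depths")
    track.lower = np.interp(track.window_depth, bounds.depths, bounds.lower)
    track.upper = np.interp(track.window_depth, bounds.depths, bounds.upper)
    return track


def call_regions_ci(track: AssociationTrack, bounds: NullBounds | None = None,
                    grid: int = 10_000, merge_gap: int | None = None,
                    trait: str | None = None) -> list[Region]:
    """Regions where the window mean Δ escapes the null bounds.

    Windows with fitted Δ strictly outside (lower, upper) at their mean
    depth are snapped to the grid and merged exactly as in the ED caller.
    Each region records the sign of its mean Δ (direction of parental
    contribution).
    """
    if bounds is not None:
        attach_bounds(track, bounds)
    if track.lower is None or track.upper is None:
        raise ValueError("no bounds on track and none supplied")
    if merge_gap is None:
        merge_gap = grid
    prov = frozenset({(track.statistic_kind, track.marker_kind)})
    out: list[Region] = []
    outside = (track.fitted > track.upper) | (track.fitted < track.lower)
    for chrom in sorted(set(track.chroms.tolist())):
        m = (track.chroms == chrom) & outside
        if not m.any():
            continue
        pos_out = track.positions[m]
        val_out = track.fitted[m]
        bins = np.unique((pos_out // grid) * grid)
        for s, e in _merge_bins(bins, grid, merge_gap):
            inside = (pos_out >= s) & (pos_out < e)
            sign = int(math.copysign(1, val_out[inside].mean()))
            out.append(Region(chrom, s, e, trait=trait, provenance=prov, sign=sign))
    return out
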