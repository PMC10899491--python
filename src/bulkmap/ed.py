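"""Euclidean-distance (ED) association statistic for pooled bulks.

At each variant site the per-base read frequencies of the two bulks are
compared by their Euclidean distance

    D = sqrt( sum_b (Nmut_b - Nwt_b)^2 )

where ``Nmut_b`` / ``Nwt_b`` are the frequencies of base ``b`` in the
high- and low-phenotype pools. D is symmetric, approaches 0 at unlinked
loci, and is bounded by sqrt(2) at a biallelic site. Raising D to the 5th
power suppresses background noise; the powered values are smoothed along
each chromosome with a tricube-kernel local weighted mean over physical
distance, and the genome-wide threshold is median + 3 sample SD of the
fitted values. Sites above threshold are snapped to a 10-kb grid and
merged into candidate regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .regions import Region
from .vario import VariantTable

SQRT2 = float(np.sqrt(2.0))


@dataclass
class AssociationTrack:
    """Per-site association statistic along the genome.

    Parallel arrays sorted by (chrom, pos). ``threshold`` is the scalar
    genome-wide cutoff in ED mode; ΔSNP-index tracks carry per-site bounds
    instead (see :mod:`bulkmap.snpindex`).
    """

    chroms: np.ndarray  # str per site
    positions: np.ndarray  # bp, ascending within chrom
    raw: np.ndarray
    fitted: np.ndarray
    statistic_kind: str = "ED5"
    marker_kind: str = "SNP"
    threshold: float | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    window_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.positions)
        if len(self.chroms) != n or len(self.raw) != n or len(self.fitted) != n:
            raise ValueError("track arrays must have equal length")
        for chrom in np.unique(self.chroms):
            pos = self.positions[self.chroms == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def for_chrom(self, chrom: str) -> "AssociationTrack":
        m = self.chroms == chrom
        return AssociationTrack(
            self.chroms[m], self.positions[m], self.raw[m], self.fitted[m],
            self.statistic_kind, self.marker_kind, self.threshold,
            None if self.lower is None else self.lower[m],
            None if self.upper is None else self.upper[m],
            None if self.window_depth is None else self.window_depth[m],
        )


def ed_value(freq_mut: np.ndarray, freq_wt: np.ndarray) -> float:
    """Euclidean distance between two per-base frequency vectors.

    Each vector must sum to 1 (within 1e-9). Symmetric in its arguments;
    for biallelic sites the result lies in [0, sqrt(2)].
    """
    m = np.asarray(freq_mut, dtype=float)
    w = np.asarray(freq_wt, dtype=float)
    if m.shape != w.shape:
        raise ValueError("frequency vectors must share base support")
    for v in (m, w):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequency vector sums to {v.sum()}, not 1")
    return float(np.sqrt(((m - w) ** 2).sum()))


def ed_power(d: float | np.ndarray, k: int = 5):
    """The association value: ED raised to the k-th power (default 5)."""
    return np.asarray(d, dtype=float) ** k if np.ndim(d) else float(d) ** k


def fit_track(positions: np.ndarray, values: np.ndarray,
              bandwidth_bp: float = 2_000_000.0) -> np.ndarray:
    """Tricube-kernel local weighted mean over physical distance.

    fitted_i = sum_j w_ij v_j / sum_j w_ij with
    w_ij = (1 - (d_ij/h)^3)^3 for d_ij < h, else 0. A single-site
    chromosome returns its raw value with a warning. Constant input maps
    to constant output.
    """
    pos = np.asarray(positions, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pos.size != vals.size:
        raise ValueError("positions and values must have equal length")
    if pos.size == 0:
        return np.array([])
    if pos.size == 1:
        warnings.warn("single-site chromosome: fitted = raw", stacklevel=2)
        return vals.copy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be ascending")
    h = float(bandwidth_bp)
    fitted = np.empty_like(vals)
    lo = np.searchsorted(pos, pos - h, side="right")  # first index with d < h
    hi = np.searchsorted(pos, pos + h, side="left")
    for i in range(pos.size):
        d = np.abs(pos[lo[i]:hi[i]] - pos[i])
        w = (1.0 - (d / h) ** 3) ** 3
        fitted[i] = np.dot(w, vals[lo[i]:hi[i]]) / w.sum()
    return fitted


def ed_threshold(fitted: np.ndarray) -> float:
    """Genome-wide cutoff: median + 3 sample SDs of the fitted values."""
    f = np.asarray(fitted, dtype=float)
    if f.size < 2:
        raise ValueError("threshold needs >= 2 fitted values")
    return float(np.median(f) + 3.0 * np.std(f, ddof=1))


def _merge_bins(bins: np.ndarray, grid: int, merge_gap: int) -> list[tuple[int, int]]:
    """Merge sorted 10-kb bin starts into half-open intervals."""
    out: list[tuple[int, int]] = []
    cur_s = cur_e = None
    for b in bins:
        b = int(b)
        if cur_e is not None and b - cur_e <= merge_gap:
            cur_e = b + grid
        else:
            if cur_e is not None:
                out.append((cur_s, cur_e))
            cur_s, cur_e = b, b + grid
    if cur_e is not None:
        out.append((cur_s, cur_e))
    return out


def call_regions(track: AssociationTrack, threshold: float | None = None,
                 grid: int = 10_000, merge_gap: int | None = None,
                 trait: str | None = None) -> list[Region]:
    """Candidate regions: above-threshold sites snapped to a grid, merged.

    Sites with fitted value strictly above *threshold* are assigned to the
    bin ``[floor(pos/grid)*grid, +grid)``; bins whose gap is at most
    *merge_gap* (default: one grid unit, so directly adjacent bins chain)
    are merged. Returns half-open regions; empty list if nothing exceeds
    the threshold.
    """
    thr = track.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("no threshold on track and none supplied")
    if merge_gap is None:
        merge_gap = grid
    prov = frozenset({(track.statistic_kind, track.marker_kind)})
    regions: list[Region] = []
    for chrom in sorted(set(track.chroms.tolist())):
        m = (track.chroms == chrom) & (track.fitted > thr)
        if not m.any():
            continue
        bins = np.unique((track.positions[m] // grid) * grid)
        for s, e in _merge_bins(bins, grid, merge_gap):
            regions.append(Region(chrom, s, e, trait=trait, provenance=prov))
    return regions


# ---------------------------------------------------------------------------
# Track construction from a filtered variant table

def bulk_frequencies(ad: tuple[int, ...]) -> np.ndarray:
    """(ref, alt) base-frequency vector from an allele-depth pair."""
    tot = ad[0] + ad[1]
    if tot == 0:
        raise ValueError("zero-depth site")
    return np.array([ad[0] / tot, ad[1] / tot])


def ed_track(table: VariantTable, marker_kind: str = "SNP", power: int = 5,
             bandwidth_bp: float = 2_000_000.0) -> AssociationTrack:
    """Compute the fitted ED^power track for one marker class.

    The high-phenotype pool plays the "mutant" role and the low pool the
    "wild-type" role; ED is symmetric so region calls do not depend on
    this labeling. The threshold is computed genome-wide over all fitted
    values of the marker class.
    """
    recs = [r for r in table.of_kind(marker_kind)
            if r.low_depth > 0 and r.high_depth > 0]
    chroms = np.array([r.chrom for r in recs])
    positions = np.array([r.pos for r in recs], dtype=np.int64)
    raw = np.array([
        ed_power(ed_value(bulk_frequencies(r.high_ad), bulk_frequencies(r.low_ad)),
                 power)
        for r in recs
    ])
    fitted = np.empty_like(raw)
    for chrom in np.unique(chroms):
        m = chroms == chrom
        fitted[m] = fit_track(positions[m], raw[m], bandwidth_bp)
    track = AssociationTrack(chroms, positions, raw, fitted,
                             statistic_kind=f"ED{power}", marker_kind=marker_kind)
    if len(recs) >= 2:
        track.threshold = ed_threshold(fitted)
    return track
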