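"""Interval algebra over candidate regions.

Regions are half-open ``[start, end)`` intervals in 0-based bp, so the Mb
size of a region is exactly ``(end - start) / 1e6`` — the convention that
makes published candidate-region tables' sizes reproducible from their
printed bounds. Operations: union, intersection across tracks, exclusion
of chromosomes or intervals (with splitting), total sizes, and per-region
gene counting against a GFF3/BED annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval with analysis provenance.

    ``provenance`` records which (algorithm, marker kind) tracks support
    the interval; ``sign`` optionally records the direction of the pooled
    allele-frequency difference for ΔSNP-index regions.
    """

    chrom: str
    start: int
    end: int
    trait: str | None = None
    provenance: frozenset = frozenset()
    gene_count: int | None = None
    sign: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise ValueError("region start must be >= 0")

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def overlaps(self, other: "Region") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


def _common_trait(regions: Iterable[Region]) -> str | None:
    traits = {r.trait for r in regions}
    return traits.pop() if len(traits) == 1 else None


def _merged_union(regions: Sequence[Region]) -> list[Region]:
    """Coordinate-sorted, overlap-free union of one collection."""
    out: list[Region] = []
    for chrom in sorted({r.chrom for r in regions}):
        group = sorted((r for r in regions if r.chrom == chrom),
                       key=lambda r: (r.start, r.end))
        cur_start, cur_end = group[0].start, group[0].end
        members = [group[0]]
        for r in group[1:]:
            if r.start <= cur_end:  # touching intervals merge
                cur_end = max(cur_end, r.end)
                members.append(r)
            else:
                out.append(Region(chrom, cur_start, cur_end,
                                  trait=_common_trait(members),
                                  provenance=frozenset().union(*(m.provenance for m in members))))
                cur_start, cur_end, members = r.start, r.end, [r]
        out.append(Region(chrom, cur_start, cur_end,
                          trait=_common_trait(members),
                          provenance=frozenset().union(*(m.provenance for m in members))))
    return out


def union_regions(*region_sets: Sequence[Region]) -> list[Region]:
    """Union across region sets: merged, sorted, overlap-free intervals.

    Provenance of each output interval is the union over its contributors;
    the trait label survives only if all contributors agree.
    """
    pooled = [r for rs in region_sets for r in rs]
    if not pooled:
        return []
    return _merged_union(pooled)


def intersect_tracks(region_sets: Sequence[Sequence[Region]]) -> list[Region]:
    """Set-theoretic intersection of the unions of each input region set.

    This is the "shared regions" operation: a position belongs to the
    output iff it is covered by every input set. Provenance is merged from
    the overlapping contributors. An empty intersection is allowed.
    """
    if len(region_sets) < 2:
        raise ValueError("intersection needs at least 2 region sets")
    current = _merged_union(list(region_sets[0])) if region_sets[0] else []
    for other_set in region_sets[1:]:
        if not current or not other_set:
            return []
        other = _merged_union(list(other_set))
        nxt: list[Region] = []
        for a in current:
            for b in other:
                if a.overlaps(b):
                    nxt.append(Region(
                        a.chrom, max(a.start, b.start), min(a.end, b.end),
                        trait=_common_trait([a, b]),
                        provenance=a.provenance | b.provenance,
                    ))
        current = _merged_union(nxt) if nxt else []
    return current


def exclude(regions: Sequence[Region], drop_chroms: Iterable[str] = (),
            drop_intervals: Sequence[Region] = ()) -> list[Region]:
    """Remove whole chromosomes and/or subtract intervals (may split)."""
    drop_chroms = set(drop_chroms)
    out: list[Region] = []
    for r in regions:
        if r.chrom in drop_chroms:
            continue
        pieces = [(r.start, r.end)]
        for d in drop_intervals:
            if d.chrom != r.chrom:
                continue
            nxt: list[tuple[int, int]] = []
            for s, e in pieces:
                if d.end <= s or d.start >= e:
                    nxt.append((s, e))
                    continue
                if d.start > s:
                    nxt.append((s, d.start))
                if d.end < e:
                    nxt.append((d.end, e))
            pieces = nxt
        for s, e in pieces:
            out.append(replace(r, start=s, end=e))
    return out


def total_size_mb(regions: Sequence[Region]) -> float:
    """Total span in Mb at full precision (round only when reporting)."""
    return sum(r.end - r.start for r in regions) / 1e6


# ---------------------------------------------------------------------------
# Gene annotation

@dataclass
class GeneAnnotation:
    """Gene id + half-open interval records, sorted internally."""

    records: list[tuple[str, str, int, int]]  # (gene_id, chrom, start, end)

    def __post_init__(self) -> None:
        for gid, chrom, start, end in self.records:
            if start >= end:
                raise ValueError(f"empty gene interval {gid} {chrom}:{start}-{end}")
        self.records = sorted(self.records, key=lambda t: (t[1], t[2], t[3]))

    def __len__(self) -> int:
        return len(self.records)


def read_gff3(path: str | Path, feature_type: str = "gene") -> GeneAnnotation:
    """Load gene records from a GFF3 file (1-based inclusive -> half-open)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    records = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        records.append((gid, feat.seqid, feat.start - 1, feat.end))
    return GeneAnnotation(records)


def count_genes(regions: Sequence[Region], annotation: GeneAnnotation,
                mode: str = "overlap") -> list[Region]:
    """Annotate each region with its gene count.

    ``mode="overlap"`` counts a gene if it overlaps the region by >= 1 bp
    (a gene spanning two regions counts once per region);
    ``mode="midpoint"`` counts a gene whose interval midpoint falls inside
    the region.
    """
    if mode not in ("overlap", "midpoint"):
        raise ValueError("mode must be 'overlap' or 'midpoint'")
    out = []
    for r in regions:
        n = 0
        for _gid, chrom, gs, ge in annotation.records:
            if chrom != r.chrom:
                continue
            if mode == "overlap":
                hit = gs < r.end and r.start < ge
            else:
                mid = (gs + ge) / 2.0
                hit = r.start <= mid < r.end
            n += hit
        out.append(replace(r, gene_count=n))
    return out


def total_gene_count(regions: Sequence[Region], annotation: GeneAnnotation,
                     mode: str = "overlap") -> int:
    """Deduplicated gene total across a region set."""
    genes: set[str] = set()
    for r in regions:
        for gid, chrom, gs, ge in annotation.records:
            if chrom != r.chrom:
                continue
            if mode == "overlap":
                hit = gs < r.end and r.start < ge
            else:
                mid = (gs + ge) / 2.0
                hit = r.start <= mid < r.end
            if hit:
                genes.add(gid)
    return len(genes)


# ---------------------------------------------------------------------------
# I/O and reporting

def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            name = ";".join(sorted(f"{a}:{m}" for a, m in r.provenance)) or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def read_bed(path: str | Path, trait: str | None = None) -> list[Region]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), trait=trait))
    return regions


def region_report(regions: Sequence[Region]) -> pd.DataFrame:
    """Human-readable table (Mb sizes rounded to 2 decimals)."""
    return pd.DataFrame(
        dict(
            trait=[r.trait for r in regions],
            chrom=[r.chrom for r in regions],
            start=[r.start for r in regions],
            end=[r.end for r in regions],
            size_mb=[round(r.size_mb, 2) for r in regions],
            gene_number=[r.gene_count for r in regions],
        )
    )
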