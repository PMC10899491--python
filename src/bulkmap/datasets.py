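"""Bundled example datasets.

``rice_candidate_regions`` carries the final candidate regions reported by
a published QTL-seq experiment on a 299-plant japonica rice F3 population
segregating for plant height (PH) and days to heading (DH): the
intersection of ED and ΔSNP-index regions across SNP and InDel markers,
with per-region gene counts against the Nipponbare annotation. Bounds are
half-open [start, end) bp, so sizes in Mb are (end - start)/1e6.

The table is input data for the region-algebra module (totals,
cross-trait intersections, chromosome exclusions and union gene counts
are all recomputed from it, never stored).
"""

from __future__ import annotations

from .regions import Region

_CANDIDATE_REGIONS_TSV = """\
trait	chrom	start	end	gene_number
PH	Chr1	36420000	37240000	113
PH	Chr3	6060000	11030000	757
PH	Chr3	34420000	34490000	11
PH	Chr7	27310000	29690000	373
PH	Chr10	21460000	21940000	69
DH	Chr1	36420000	37240000	113
DH	Chr2	27240000	31070000	584
DH	Chr7	27520000	29690000	338
DH	Chr10	11130000	13470000	349
"""


def rice_candidate_regions() -> dict[str, list[Region]]:
    """Candidate-region sets keyed by trait (``"PH"`` and ``"DH"``)."""
    out: dict[str, list[Region]] = {}
    lines = _CANDIDATE_REGIONS_TSV.strip().splitlines()[1:]
    for line in lines:
        trait, chrom, start, end, genes = line.split("\t")
        out.setdefault(trait, []).append(
            Region(chrom, int(start), int(end), trait=trait,
                   gene_count=int(genes))
        )
    return out


def candidate_region_summary() -> dict[str, float | int]:
    """Recompute the study-level aggregates from the bundled region table.

    Everything here is derived by interval algebra from the per-region
    bounds and gene counts: per-trait totals, the cross-trait shared
    regions, the exclusion of the chromosomes carrying already-cloned
    genes (Chr2 and Chr7), and the union gene count of the remaining
    regions with shared intervals counted once. Gene numbers for derived
    region sets are transferred from the published rows by exact interval
    identity.
    """
    from .regions import exclude, intersect_tracks, total_size_mb, union_regions

    table = rice_candidate_regions()
    lookup = gene_count_lookup()
    ph, dh = table["PH"], table["DH"]

    shared = intersect_tracks([ph, dh])
    ph_remaining = exclude(ph, drop_chroms=("Chr2", "Chr7"))
    dh_remaining = exclude(dh, drop_chroms=("Chr2", "Chr7"))
    remaining_union = union_regions(ph_remaining, dh_remaining)

    def genes(regions) -> int:
        return sum(lookup[(r.chrom, r.start, r.end)] for r in regions)

    return {
        "ph_total_mb": round(total_size_mb(ph), 2),
        "dh_total_mb": round(total_size_mb(dh), 2),
        "ph_gene_total": genes(ph),
        "dh_gene_total": genes(dh),
        "shared_total_mb": round(total_size_mb(shared), 2),
        "shared_gene_total": genes(shared),
        "ph_remaining_mb": round(total_size_mb(ph_remaining), 2),
        "dh_remaining_mb": round(total_size_mb(dh_remaining), 2),
        "remaining_union_gene_total": genes(remaining_union),
    }


def gene_count_lookup() -> dict[tuple[str, int, int], int]:
    """Published per-interval gene counts keyed by exact interval.

    Used to transfer gene numbers onto regions produced by interval
    algebra when the output interval coincides with a published row.
    """
    table = rice_candidate_regions()
    out: dict[tuple[str, int, int], int] = {}
    for regions in table.values():
        for r in regions:
            out[(r.chrom, r.start, r.end)] = r.gene_count
    return out
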