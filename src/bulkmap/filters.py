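"""Hard filters applied to pooled variant tables before association.

Six independent passes, applied in a fixed, logged order:

1. quality      — drop QUAL < 30 or QD < 2.0 (records with no QD pass the
                  QD test; they are counted separately in the log)
2. proximity    — drop SNPs within 5 bp of an InDel, and both members of
                  any InDel pair within 10 bp
3. clusters     — drop every member of a run of more than 2 variants
                  chained by gaps of <= 5 bp
4. biallelic    — keep only sites with exactly one ALT allele and no
                  third-allele read support in either bulk
5. depth        — keep sites where each bulk's total depth is >= 4
6. parents      — keep sites where both parents are homozygous for
                  different alleles and every bulk allele above the error
                  floor is carried by a parent

Each filter is idempotent and returns a new table; :func:`apply_filters`
runs the whole chain and returns removal counts per pass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .vario import PooledVariant, VariantTable


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 30.0
    min_qd: float = 2.0
    snp_indel_dist: int = 5
    indel_indel_dist: int = 10
    cluster_window: int = 5
    cluster_max: int = 2
    min_bulk_depth: int = 4
    seq_error_rate: float = 0.001

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_qd", "snp_indel_dist", "indel_indel_dist",
                     "cluster_window", "cluster_max", "min_bulk_depth",
                     "seq_error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_quality(table: VariantTable, cfg: FilterConfig = FilterConfig()) -> VariantTable:
    """Keep records with QUAL >= min_qual and QD >= min_qd.

    Thresholds remove strictly-below values, so QUAL 30 / QD 2.0 survive.
    Records lacking QD pass the QD test.
    """
    kept = [
        r for r in table
        if r.qual >= cfg.min_qual and (r.qd is None or r.qd >= cfg.min_qd)
    ]
    return table.with_records(kept, "quality")


def filter_proximity(table: VariantTable, cfg: FilterConfig = FilterConfig()) -> VariantTable:
    """Drop SNPs near InDels and mutually adjacent InDels.

    A SNP within ``snp_indel_dist`` bp of any InDel is removed (the InDel
    stays); both members of an InDel pair within ``indel_indel_dist`` bp
    are removed. Distance is the absolute position difference on the same
    chromosome.
    """
    snps = [(i, r) for i, r in enumerate(table) if r.kind == "SNP"]
    indels = [(i, r) for i, r in enumerate(table) if r.kind == "InDel"]
    drop: set[int] = set()
    by_chrom: dict[str, list[tuple[int, PooledVariant]]] = {}
    for i, r in indels:
        by_chrom.setdefault(r.chrom, []).append((i, r))
    for i, r in snps:
        for j, q in by_chrom.get(r.chrom, ()):
            if abs(r.pos - q.pos) <= cfg.snp_indel_dist:
                drop.add(i)
                break
    for chrom, group in by_chrom.items():
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                if abs(group[a][1].pos - group[b][1].pos) <= cfg.indel_indel_dist:
                    drop.add(group[a][0])
                    drop.add(group[b][0])
                elif group[b][1].pos - group[a][1].pos > cfg.indel_indel_dist:
                    break
    kept = [r for i, r in enumerate(table) if i not in drop]
    return table.with_records(kept, "proximity")


def filter_clusters(table: VariantTable, cfg: FilterConfig = FilterConfig()) -> VariantTable:
    """Remove whole runs of more than ``cluster_max`` variants chained by
    gaps of <= ``cluster_window`` bp (all marker kinds counted together)."""
    drop: set[int] = set()
    run: list[int] = []
    prev: PooledVariant | None = None
    indices = list(range(len(table)))

    def flush() -> None:
        if len(run) > cfg.cluster_max:
            drop.update(run)

    for i in indices:
        r = table[i]
        if prev is not None and r.chrom == prev.chrom and \
                r.pos - prev.pos <= cfg.cluster_window:
            run.append(i)
        else:
            flush()
            run = [i]
        prev = r
    flush()
    kept = [r for i, r in enumerate(table) if i not in drop]
    return table.with_records(kept, "clusters")


def _third_allele_support(r: PooledVariant) -> bool:
    for ad in (r.low_ad, r.high_ad):
        if any(d > 0 for d in ad[2:]):
            return True
    return False


def filter_biallelic(table: VariantTable) -> VariantTable:
    """Keep only strictly biallelic sites (one ALT, no extra-allele reads
    in either bulk)."""
    kept = [
        r for r in table
        if len(r.alts) == 1 and not _third_allele_support(r)
    ]
    return table.with_records(kept, "biallelic")


def filter_depth(table: VariantTable, cfg: FilterConfig = FilterConfig()) -> VariantTable:
    """Keep sites where each bulk's total read depth is >= min_bulk_depth."""
    kept = [
        r for r in table
        if r.low_depth >= cfg.min_bulk_depth and r.high_depth >= cfg.min_bulk_depth
    ]
    return table.with_records(kept, "depth")


def _parent_consistent(r: PooledVariant, cfg: FilterConfig) -> bool:
    if r.p1_gt is None or r.p2_gt is None:
        return False
    if r.p1_gt[0] != r.p1_gt[1] or r.p2_gt[0] != r.p2_gt[1]:
        return False  # heterozygous parent: M/P attribution undefined
    a1, a2 = r.p1_gt[0], r.p2_gt[0]
    if a1 == a2:
        return False  # uninformative: parents share the allele
    floor = 2.0 * cfg.seq_error_rate
    for ad in (r.low_ad, r.high_ad):
        tot = sum(ad)
        if tot == 0:
            continue
        for allele, depth in enumerate(ad):
            if allele in (a1, a2):
                continue
            if depth / tot > floor:
                return False  # bulk allele not inherited from either parent
    return True


def filter_parent_consistency(table: VariantTable,
                              cfg: FilterConfig = FilterConfig()) -> VariantTable:
    """Keep sites informative for parental-origin bookkeeping.

    Both parents must be called homozygous for different alleles, and any
    allele observed in a bulk at a frequency above twice the sequencing
    error rate must be carried by a parent; rarer alleles are treated as
    noise.
    """
    kept = [r for r in table if _parent_consistent(r, cfg)]
    return table.with_records(kept, "parents")


#: default pass order
FILTER_CHAIN = (
    ("quality", filter_quality),
    ("proximity", filter_proximity),
    ("clusters", filter_clusters),
    ("biallelic", lambda t, cfg: filter_biallelic(t)),
    ("depth", filter_depth),
    ("parents", filter_parent_consistency),
)


def apply_filters(table: VariantTable, cfg: FilterConfig = FilterConfig()
                  ) -> tuple[VariantTable, dict[str, int]]:
    """Run the full filter chain; returns the table and per-pass removals.

    The log also records how many surviving records passed the QD test by
    absence (``qd_missing``), and input/output totals.
    """
    log: dict[str, int] = {"input": len(table)}
    log["qd_missing"] = sum(1 for r in table if r.qd is None)
    for name, fn in FILTER_CHAIN:
        before = len(table)
        table = fn(table, cfg)
        log[name] = before - len(table)
    log["output"] = len(table)
    return table, log
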