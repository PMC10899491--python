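"""Variant records for pooled bulked-segregant experiments.

The unit record of the whole pipeline is :class:`PooledVariant`: one variant
site carrying the genotypes and allele depths of the four samples of a
QTL-seq design — the two inbred parents and the two extreme-phenotype bulks.
A :class:`VariantTable` is an ordered, coordinate-sorted collection of such
records with provenance metadata.

Reading uses cyvcf2; writing is plain VCF 4.2 / TSV text with fixed
formatting so that output is byte-identical under a fixed simulator seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: canonical sample roles, in column order
ROLES = ("P1", "P2", "LOW", "HIGH")

#: largest length difference (bp) still classified as a small InDel
MAX_INDEL_LEN = 50

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _classify(ref: str, alts: Sequence[str]) -> tuple[str, bool]:
    """Classify a site as SNP / InDel / Other from its allele lengths.

    Returns ``(kind, oversize)`` where *oversize* marks length differences
    beyond the small-InDel bound (such records are retained but flagged and
    excluded from the InDel marker class).
    """
    if all(len(a) == len(ref) == 1 for a in alts):
        return "SNP", False
    diffs = [abs(len(a) - len(ref)) for a in alts]
    if any(d > MAX_INDEL_LEN for d in diffs):
        return "Other", True
    if all(d >= 1 for d in diffs):
        return "InDel", False
    # mixture of same-length (MNP-like) and length-changing alleles
    return "Other", False


@dataclass
class PooledVariant:
    """One variant site with parent and bulk genotypes and allele depths.

    Coordinates are 1-based as in VCF. ``alts`` may hold several ALT alleles
    until the biallelic filter runs; allele-depth tuples are aligned to
    ``(ref,) + alts``. Genotypes are allele-index pairs, ``None`` if missing.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float
    qd: float | None
    p1_gt: tuple[int, int] | None
    p2_gt: tuple[int, int] | None
    low_gt: tuple[int, int] | None
    high_gt: tuple[int, int] | None
    p1_ad: tuple[int, ...]
    p2_ad: tuple[int, ...]
    low_ad: tuple[int, ...]
    high_ad: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for ad in (self.p1_ad, self.p2_ad, self.low_ad, self.high_ad):
            if any(d < 0 for d in ad):
                raise ValueError(f"negative allele depth at {self.chrom}:{self.pos}")

    @property
    def kind(self) -> str:
        """``"SNP"``, ``"InDel"`` (1–50 bp) or ``"Other"``."""
        return _classify(self.ref, self.alts)[0]

    @property
    def oversize(self) -> bool:
        """True when an allele-length difference exceeds the small-InDel bound."""
        return _classify(self.ref, self.alts)[1]

    @property
    def low_depth(self) -> int:
        return sum(self.low_ad)

    @property
    def high_depth(self) -> int:
        return sum(self.high_ad)

    def is_transition(self) -> bool:
        return (
            self.kind == "SNP"
            and len(self.alts) == 1
            and frozenset((self.ref, self.alts[0])) in _TRANSITIONS
        )


@dataclass
class VariantTable:
    """Coordinate-sorted variant records plus provenance metadata."""

    records: list[PooledVariant]
    source: str = ""
    filters_applied: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        prev: tuple[str, int] | None = None
        for r in self.records:
            key = (r.chrom, r.pos, r.ref, r.alts)
            if key in seen:
                raise ValueError(f"duplicate record {r.chrom}:{r.pos} {r.ref}>{r.alts}")
            seen.add(key)
            cur = (r.chrom, r.pos)
            if prev is not None and prev[0] == cur[0] and prev[1] > cur[1]:
                raise ValueError(
                    f"records not coordinate-sorted: {r.chrom}:{r.pos} follows "
                    f"{prev[0]}:{prev[1]}"
                )
            prev = cur

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PooledVariant]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PooledVariant:
        return self.records[i]

    def with_records(self, records: Iterable[PooledVariant], filter_name: str | None = None) -> "VariantTable":
        names = self.filters_applied + ((filter_name,) if filter_name else ())
        return VariantTable(list(records), source=self.source, filters_applied=names)

    def of_kind(self, kind: str) -> list[PooledVariant]:
        return [r for r in self.records if r.kind == kind]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                dict(
                    chrom=r.chrom,
                    pos=r.pos,
                    ref=r.ref,
                    alt=",".join(r.alts),
                    kind=r.kind,
                    qual=r.qual,
                    qd=r.qd,
                    p1_gt=_fmt_gt(r.p1_gt),
                    p2_gt=_fmt_gt(r.p2_gt),
                    low_gt=_fmt_gt(r.low_gt),
                    high_gt=_fmt_gt(r.high_gt),
                    p1_ad=",".join(map(str, r.p1_ad)),
                    p2_ad=",".join(map(str, r.p2_ad)),
                    low_ad=",".join(map(str, r.low_ad)),
                    high_ad=",".join(map(str, r.high_ad)),
                )
            )
        return pd.DataFrame(rows)


def _fmt_gt(gt: tuple[int, int] | None) -> str:
    return "./." if gt is None else f"{gt[0]}/{gt[1]}"


def _parse_gt(s: str) -> tuple[int, int] | None:
    s = s.replace("|", "/")
    if s in (".", "./."):
        return None
    a, b = s.split("/")
    return (int(a), int(b))


# ---------------------------------------------------------------------------
# VCF input

def read_vcf(path: str | Path, sample_roles: Mapping[str, str] | None = None) -> VariantTable:
    """Read a 4-sample VCF into a :class:`VariantTable`.

    Parameters
    ----------
    path
        VCF 4.x file, plain or bgzipped.
    sample_roles
        Maps each role in ``("P1", "P2", "LOW", "HIGH")`` to a sample name in
        the VCF. Defaults to the identity mapping.

    Multi-allelic rows are kept (one record per row, all ALTs retained) so
    that downstream filter accounting is staged explicitly. Missing QD is
    recorded as ``None``, never coerced to zero. An unsorted VCF raises,
    naming the first offending record.
    """
    from cyvcf2 import VCF

    roles = dict(sample_roles) if sample_roles else {r: r for r in ROLES}
    missing_roles = [r for r in ROLES if r not in roles]
    if missing_roles:
        raise ValueError(f"sample_roles missing roles: {missing_roles}")

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    try:
        idx = {role: samples.index(name) for role, name in roles.items()}
    except ValueError as exc:
        raise ValueError(f"sample not found in VCF {path}: {exc}") from None

    records: list[PooledVariant] = []
    prev: tuple[str, int] | None = None
    for v in vcf:
        cur = (v.CHROM, v.POS)
        if prev is not None and prev[0] == cur[0] and prev[1] > cur[1]:
            raise ValueError(
                f"VCF not coordinate-sorted: {cur[0]}:{cur[1]} follows {prev[0]}:{prev[1]}"
            )
        prev = cur
        gts = v.genotypes  # [[a, b, phased], ...]
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"AD missing at {v.CHROM}:{v.POS}")
        qd = v.INFO.get("QD")

        def gt_of(role: str) -> tuple[int, int] | None:
            a, b = gts[idx[role]][0], gts[idx[role]][1]
            if a < 0 or b < 0:
                return None
            return (int(a), int(b))

        def ad_of(role: str) -> tuple[int, ...]:
            row = ad[idx[role]]
            return tuple(int(x) if x >= 0 else 0 for x in np.atleast_1d(row))

        records.append(
            PooledVariant(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else math.nan,
                qd=float(qd) if qd is not None else None,
                p1_gt=gt_of("P1"),
                p2_gt=gt_of("P2"),
                low_gt=gt_of("LOW"),
                high_gt=gt_of("HIGH"),
                p1_ad=ad_of("P1"),
                p2_ad=ad_of("P2"),
                low_ad=ad_of("LOW"),
                high_ad=ad_of("HIGH"),
            )
        )
    return VariantTable(records, source=str(path))


# ---------------------------------------------------------------------------
# VCF output (fixed-format text; byte-deterministic)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bulkmap
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
"""


def write_vcf(table: VariantTable, path: str | Path, contigs: Sequence[tuple[str, int]] | None = None) -> None:
    """Write a 4-sample VCF (samples P1, P2, LOW, HIGH; FORMAT GT:AD:DP)."""
    lines = [_VCF_HEADER]
    for name, length in contigs or ():
        lines.append(f"##contig=<ID={name},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 "FORMAT\tP1\tP2\tLOW\tHIGH\n")
    for r in table:
        info = f"QD={r.qd:.2f}" if r.qd is not None else "."
        cols = [
            r.chrom,
            str(r.pos),
            ".",
            r.ref,
            ",".join(r.alts),
            f"{r.qual:.2f}",
            "PASS",
            info,
            "GT:AD:DP",
        ]
        for gt, ad in (
            (r.p1_gt, r.p1_ad),
            (r.p2_gt, r.p2_ad),
            (r.low_gt, r.low_ad),
            (r.high_gt, r.high_ad),
        ):
            cols.append(f"{_fmt_gt(gt)}:{','.join(map(str, ad))}:{sum(ad)}")
        lines.append("\t".join(cols) + "\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# TSV round trip

def write_tsv(table: VariantTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv(path: str | Path) -> VariantTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     dtype={"chrom": str, "ref": str, "alt": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PooledVariant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alts=tuple(row.alt.split(",")),
                qual=float(row.qual),
                qd=None if pd.isna(row.qd) else float(row.qd),
                p1_gt=_parse_gt(row.p1_gt),
                p2_gt=_parse_gt(row.p2_gt),
                low_gt=_parse_gt(row.low_gt),
                high_gt=_parse_gt(row.high_gt),
                p1_ad=tuple(int(x) for x in row.p1_ad.split(",")),
                p2_ad=tuple(int(x) for x in row.p2_ad.split(",")),
                low_ad=tuple(int(x) for x in row.low_ad.split(",")),
                high_ad=tuple(int(x) for x in row.high_ad.split(",")),
            )
        )
    return VariantTable(records, source=str(path))


# ---------------------------------------------------------------------------
# QC summary

def qc_summary(table: VariantTable) -> dict:
    """Per-sample variant counts, Ts/Tv ratio and heterozygosity ratios.

    Ts/Tv is computed over biallelic SNP sites (transitions A<->G, C<->T);
    it is reported as ``None`` when no transversions are present. The
    heterozygosity ratio of a sample is het calls / called genotypes over
    all sites.
    """
    if len(table) == 0:
        raise ValueError("qc_summary requires a nonempty table")
    ts = tv = 0
    per_sample: dict[str, dict] = {
        role: {"snp": 0, "indel": 0, "het": 0, "called": 0} for role in ROLES
    }
    gt_attrs = {"P1": "p1_gt", "P2": "p2_gt", "LOW": "low_gt", "HIGH": "high_gt"}
    for r in table:
        if r.kind == "SNP" and len(r.alts) == 1:
            if r.is_transition():
                ts += 1
            else:
                tv += 1
        for role, attr in gt_attrs.items():
            gt = getattr(r, attr)
            if gt is None:
                continue
            s = per_sample[role]
            s["called"] += 1
            if gt[0] != gt[1]:
                s["het"] += 1
            if gt != (0, 0):
                if r.kind == "SNP":
                    s["snp"] += 1
                elif r.kind == "InDel":
                    s["indel"] += 1
    out = {
        "n_sites": len(table),
        "ts": ts,
        "tv": tv,
        "ts_tv": (ts / tv) if tv > 0 else None,
        "samples": {},
    }
    for role, s in per_sample.items():
        out["samples"][role] = {
            "snp_count": s["snp"],
            "indel_count": s["indel"],
            "het_ratio": (s["het"] / s["called"]) if s["called"] else None,
        }
    return out
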