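"""Forward simulation of a bulked-segregant QTL-seq experiment.

Emulates a biparental japonica-rice style design: two fully homozygous,
fully divergent inbred parents are crossed; the F1 is selfed to F2 and,
optionally, once more to F3 (one selfed seed per independent F2 plant by
default). A quantitative trait is assigned under a purely additive model
with Gaussian noise scaled to a target heritability. The extreme tails of
the phenotype distribution are pooled and the pools are "sequenced" by
drawing pooled read counts at every parent-divergent marker, producing a
4-sample variant table (P1, P2, LOW, HIGH) plus the ground truth needed to
score recovery.

Meiosis follows a Haldane model: the crossover count per chromosome is
Poisson(length_Mb * cM_per_Mb / 100) with breakpoints uniform along the
chromosome. The recombination map is uniform; 4 cM/Mb is a rice-typical
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .vario import PooledVariant, VariantTable, write_vcf


# ---------------------------------------------------------------------------
# Specs

@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome layout, marker grid and uniform recombination rate.

    Markers are placed every ``marker_spacing`` bp starting at
    ``marker_spacing`` (so a 1 Mb chromosome at 100 kb spacing carries 10
    markers). Every marker is parent-divergent by construction.
    """

    chromosomes: tuple[tuple[str, int], ...]
    marker_spacing: int = 20_000
    cm_per_mb: float = 4.0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.marker_spacing <= 0:
            raise ValueError("marker_spacing must be > 0")
        if self.cm_per_mb < 0:
            raise ValueError("cm_per_mb must be >= 0")

    def marker_positions(self, chrom: str) -> np.ndarray:
        """1-based marker positions on *chrom* (ascending)."""
        length = dict(self.chromosomes)[chrom]
        return np.arange(self.marker_spacing, length + 1, self.marker_spacing,
                         dtype=np.int64)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class QTLSpec:
    """A single additive locus: +effect trait units per alt-allele copy."""

    chrom: str
    pos: int
    additive_effect: float
    trait: str = "PH"

    def __post_init__(self) -> None:
        if not np.isfinite(self.additive_effect):
            raise ValueError("QTL effect must be finite")


@dataclass(frozen=True)
class CrossConfig:
    """Design parameters of the simulated cross and pooled sequencing.

    Defaults mirror a 299-plant F3 design with ~10% tails pooled, ~50X
    bulk coverage and ~31X parent coverage.
    """

    n_individuals: int = 299
    generation: str = "F3"
    pool_fraction: float = 0.10
    heritability: float = 0.5
    bulk_depth_mean: float = 50.0
    parent_depth_mean: float = 31.0
    seq_error_rate: float = 0.001
    seed: int = 0
    n_f2_families: int | None = None  # None: one F3 per independent F2 plant

    def __post_init__(self) -> None:
        if self.generation not in ("F2", "F3"):
            raise ValueError("generation must be 'F2' or 'F3'")
        if not (0.0 < self.pool_fraction <= 0.5):
            raise ValueError("pool_fraction must be in (0, 0.5]")
        if not (0.0 <= self.heritability <= 1.0):
            raise ValueError("heritability must be in [0, 1]")
        if self.bulk_depth_mean <= 0 or self.parent_depth_mean <= 0:
            raise ValueError("sequencing depths must be > 0")
        if not (0.0 <= self.seq_error_rate < 0.5):
            raise ValueError("seq_error_rate must be in [0, 0.5)")


@dataclass
class TruthTable:
    """Ground truth of one simulated experiment (the recovery oracle)."""

    qtls: list[QTLSpec]
    dosages: np.ndarray  # (n_individuals, n_qtls) alt-allele dosage at QTLs
    phenotypes: np.ndarray
    low_ids: np.ndarray
    high_ids: np.ndarray

    def write_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            dict(
                chrom=[q.chrom for q in self.qtls],
                pos=[q.pos for q in self.qtls],
                effect=[q.additive_effect for q in self.qtls],
                trait=[q.trait for q in self.qtls],
            )
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Haplotypes and meiosis

@dataclass
class Individual:
    """Diploid genotype: per chromosome, two haplotype arrays over markers.

    Haplotype values are 0 (parent-1 / ref allele) or 1 (parent-2 / alt).
    """

    haplotypes: dict[str, np.ndarray]  # chrom -> (2, n_markers) uint8

    def dosage(self, chrom: str, marker_index: int) -> int:
        h = self.haplotypes[chrom]
        return int(h[0, marker_index] + h[1, marker_index])


def make_parents(genome: GenomeSpec, seed: int = 0) -> tuple[Individual, Individual]:
    """Two fully homozygous, fully divergent inbred parents.

    Parent 1 carries the ref allele at every marker, parent 2 the alt.
    Raises if any chromosome carries zero markers (spacing > length).
    """
    haps1: dict[str, np.ndarray] = {}
    haps2: dict[str, np.ndarray] = {}
    for name, _length in genome.chromosomes:
        pos = genome.marker_positions(name)
        if pos.size == 0:
            raise ValueError(
                f"marker_spacing {genome.marker_spacing} leaves zero markers "
                f"on chromosome {name}"
            )
        haps1[name] = np.zeros((2, pos.size), dtype=np.uint8)
        haps2[name] = np.ones((2, pos.size), dtype=np.uint8)
    return Individual(haps1), Individual(haps2)


def simulate_gamete(parent: Individual, genome: GenomeSpec,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One recombinant gamete (per-chromosome haplotype arrays).

    Haldane model: crossover count ~ Poisson(morgans) per chromosome with
    breakpoints uniform in physical position; the starting haplotype is
    chosen with probability 1/2. With ``cm_per_mb == 0`` the gamete is one
    intact input haplotype per chromosome.
    """
    gamete: dict[str, np.ndarray] = {}
    for name, length in genome.chromosomes:
        hap = parent.haplotypes[name]
        pos = genome.marker_positions(name)
        morgans = (length / 1e6) * genome.cm_per_mb / 100.0
        n_co = rng.poisson(morgans)
        start = rng.integers(2)
        if n_co == 0:
            gamete[name] = hap[start].copy()
            continue
        breaks = np.sort(rng.uniform(0, length, size=n_co))
        # phase at a marker flips once per breakpoint to its left
        phase = (start + np.searchsorted(breaks, pos)) % 2
        gamete[name] = hap[phase, np.arange(pos.size)].astype(np.uint8)
    return gamete


def _self(parent: Individual, genome: GenomeSpec,
          rng: np.random.Generator) -> Individual:
    g1 = simulate_gamete(parent, genome, rng)
    g2 = simulate_gamete(parent, genome, rng)
    return Individual({c: np.stack([g1[c], g2[c]]) for c in g1})


def make_population(parents: tuple[Individual, Individual], genome: GenomeSpec,
                    config: CrossConfig) -> list[Individual]:
    """Simulate the segregating population from two inbred parents.

    F2: each individual is a selfed seed of the F1. F3: each individual is
    one selfed seed of an independent F2 plant (so unlinked markers
    segregate 3/8 : 1/4 : 3/8), unless ``n_f2_families`` caps the number of
    distinct F2 plants, in which case F3 individuals are drawn from those
    families in round-robin order.
    """
    if config.n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    p1, p2 = parents
    for name, _ in genome.chromosomes:
        h1, h2 = parents[0].haplotypes[name], parents[1].haplotypes[name]
        if not ((h1[0] == h1[1]).all() and (h2[0] == h2[1]).all()):
            raise ValueError("parents must be homozygous")
        if not (h1[0] != h2[0]).all():
            raise ValueError("parents must be divergent at every marker")
    rng = np.random.default_rng(config.seed)
    f1 = Individual({
        name: np.stack([p1.haplotypes[name][0], p2.haplotypes[name][0]])
        for name, _ in genome.chromosomes
    })
    n = config.n_individuals
    if config.generation == "F2":
        return [_self(f1, genome, rng) for _ in range(n)]
    n_families = n if config.n_f2_families is None else config.n_f2_families
    f2_plants = [_self(f1, genome, rng) for _ in range(n_families)]
    return [_self(f2_plants[i % n_families], genome, rng) for i in range(n)]


# ---------------------------------------------------------------------------
# Phenotypes and pools

def _qtl_marker_index(genome: GenomeSpec, qtl: QTLSpec) -> int:
    pos = genome.marker_positions(qtl.chrom)
    idx = np.searchsorted(pos, qtl.pos)
    if idx >= pos.size or pos[idx] != qtl.pos:
        raise ValueError(
            f"QTL position {qtl.chrom}:{qtl.pos} does not coincide with a marker"
        )
    return int(idx)


def assign_phenotypes(population: Sequence[Individual], genome: GenomeSpec,
                      qtls: Sequence[QTLSpec], heritability: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Additive phenotypes: sum of effect*(dosage-1) plus Gaussian noise.

    The noise SD is set from the realised genetic variance so that
    var(genetic) / var(total) equals *heritability* for the sampled
    genotypes. ``heritability == 0`` (or no QTLs) gives pure unit-variance
    noise; ``heritability == 1`` requires nonzero genetic variance.

    Returns ``(phenotypes, dosages)`` with dosages of shape (n, n_qtls).
    """
    n = len(population)
    dosages = np.zeros((n, len(qtls)), dtype=np.int8)
    for j, q in enumerate(qtls):
        mi = _qtl_marker_index(genome, q)
        dosages[:, j] = [ind.dosage(q.chrom, mi) for ind in population]
    genetic = np.zeros(n)
    for j, q in enumerate(qtls):
        genetic += q.additive_effect * (dosages[:, j] - 1)
    var_g = float(np.var(genetic))
    if heritability == 0.0 or not qtls:
        if heritability == 1.0:
            raise ValueError("heritability 1 requires at least one QTL")
        return rng.normal(0.0, 1.0, size=n), dosages
    if var_g == 0.0:
        raise ValueError("zero genetic variance: cannot target heritability > 0")
    if heritability == 1.0:
        return genetic.copy(), dosages
    sigma = np.sqrt(var_g * (1.0 - heritability) / heritability)
    return genetic + rng.normal(0.0, sigma, size=n), dosages


def select_pools(phenotypes: np.ndarray, pool_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Index sets of the low and high phenotype tails.

    Pool size is round-half-up of fraction*n (299 plants at 10% -> 30 per
    pool). Ties are broken by individual index (stable sort), so with all
    phenotypes equal the pools are the first/last k individuals.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    if not np.isfinite(phenotypes).all():
        raise ValueError("phenotypes must be finite")
    if not (0.0 < pool_fraction <= 0.5):
        raise ValueError("pool_fraction must be in (0, 0.5]")
    n = phenotypes.size
    k = int(np.floor(pool_fraction * n + 0.5))
    if 2 * k > n:
        raise ValueError(f"pools of {k} would overlap in a population of {n}")
    order = np.argsort(phenotypes, kind="stable")
    return np.sort(order[:k]), np.sort(order[-k:])


# ---------------------------------------------------------------------------
# Pooled sequencing

def _observed_freq(p: np.ndarray, err: float) -> np.ndarray:
    """Alt-read probability after a symmetric per-read flip error."""
    return p * (1.0 - err) + (1.0 - p) * err


def _call_gt(alt: int, depth: int) -> tuple[int, int] | None:
    if depth == 0:
        return None
    frac = alt / depth
    if frac < 0.1:
        return (0, 0)
    if frac > 0.9:
        return (1, 1)
    return (0, 1)


_BASES = np.array(list("ACGT"))
_ALTS = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def sequence_bulks(population: Sequence[Individual], genome: GenomeSpec,
                   pools: tuple[np.ndarray, np.ndarray], config: CrossConfig,
                   rng: np.random.Generator) -> VariantTable:
    """Draw pooled read counts at every marker and build the variant table.

    Per site and sample: total depth ~ Poisson(mean depth); alt reads ~
    Binomial(depth, p') where p' is the pooled alt-allele frequency
    perturbed by the symmetric sequencing error. Parents are sequenced at
    their (fixed) allele frequencies. Ref/alt bases are drawn uniformly, so
    the expected Ts/Tv of the output is 0.5. QUAL and QD are synthetic
    plumbing drawn above typical hard-filter defaults.
    """
    low_ids, high_ids = pools
    if len(low_ids) == 0 or len(high_ids) == 0:
        raise ValueError("empty pool")
    err = config.seq_error_rate
    records: list[PooledVariant] = []
    for name, _length in genome.chromosomes:
        pos = genome.marker_positions(name)
        m = pos.size
        dos = np.stack([ind.haplotypes[name].sum(axis=0) for ind in population])
        p_low = dos[low_ids].mean(axis=0) / 2.0
        p_high = dos[high_ids].mean(axis=0) / 2.0
        freqs = {
            "P1": np.zeros(m),
            "P2": np.ones(m),
            "LOW": p_low,
            "HIGH": p_high,
        }
        depth_mean = {
            "P1": config.parent_depth_mean,
            "P2": config.parent_depth_mean,
            "LOW": config.bulk_depth_mean,
            "HIGH": config.bulk_depth_mean,
        }
        depth: dict[str, np.ndarray] = {}
        alt: dict[str, np.ndarray] = {}
        for s in ("P1", "P2", "LOW", "HIGH"):
            depth[s] = rng.poisson(depth_mean[s], size=m)
            alt[s] = rng.binomial(depth[s], _observed_freq(freqs[s], err))
        refs = _BASES[rng.integers(4, size=m)]
        alt_choice = rng.integers(3, size=m)
        quals = np.round(rng.uniform(600.0, 3000.0, size=m), 2)
        qds = np.round(rng.uniform(20.0, 35.0, size=m), 2)
        for i in range(m):
            ref = str(refs[i])
            records.append(
                PooledVariant(
                    chrom=name,
                    pos=int(pos[i]),
                    ref=ref,
                    alts=(_ALTS[ref][alt_choice[i]],),
                    qual=float(quals[i]),
                    qd=float(qds[i]),
                    p1_gt=_call_gt(alt["P1"][i], depth["P1"][i]),
                    p2_gt=_call_gt(alt["P2"][i], depth["P2"][i]),
                    low_gt=_call_gt(alt["LOW"][i], depth["LOW"][i]),
                    high_gt=_call_gt(alt["HIGH"][i], depth["HIGH"][i]),
                    p1_ad=(int(depth["P1"][i] - alt["P1"][i]), int(alt["P1"][i])),
                    p2_ad=(int(depth["P2"][i] - alt["P2"][i]), int(alt["P2"][i])),
                    low_ad=(int(depth["LOW"][i] - alt["LOW"][i]), int(alt["LOW"][i])),
                    high_ad=(int(depth["HIGH"][i] - alt["HIGH"][i]), int(alt["HIGH"][i])),
                )
            )
    return VariantTable(records, source="simulated")


# ---------------------------------------------------------------------------
# One-call experiment

def simulate_experiment(genome: GenomeSpec, qtls: Sequence[QTLSpec],
                        config: CrossConfig,
                        vcf_path: str | Path | None = None
                        ) -> tuple[VariantTable, TruthTable]:
    """Run the full generative model: cross, phenotype, pool, sequence.

    All randomness flows from ``config.seed``; a fixed seed yields
    byte-identical VCF output. Returns the 4-sample variant table and the
    ground-truth table.
    """
    parents = make_parents(genome, seed=config.seed)
    population = make_population(parents, genome, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    phenotypes, dosages = assign_phenotypes(
        population, genome, qtls, config.heritability, rng)
    low_ids, high_ids = select_pools(phenotypes, config.pool_fraction)
    table = sequence_bulks(population, genome, (low_ids, high_ids), config, rng)
    truth = TruthTable(list(qtls), dosages, phenotypes, low_ids, high_ids)
    if vcf_path is not None:
        write_vcf(table, vcf_path, contigs=list(genome.chromosomes))
    return table, truth


def study_design(seed: int = 0, heritability: float = 0.5,
                 qtl_effect: float | None = 1.0,
                 qtl_chrom: str = "Chr3", qtl_pos: int = 15_000_000,
                 ) -> tuple[GenomeSpec, list[QTLSpec], CrossConfig]:
    """The package's reference study design.

    5 chromosomes of 30 Mb with a marker every 20 kb, 299 F3 individuals,
    10% tails pooled (30 per pool), 50X bulks and 31X parents. Pass
    ``qtl_effect=None`` for a null (no-QTL) design.
    """
    genome = GenomeSpec(
        chromosomes=tuple((f"Chr{i}", 30_000_000) for i in range(1, 6)),
        marker_spacing=20_000,
        cm_per_mb=4.0,
    )
    qtls = [] if qtl_effect is None else [
        QTLSpec(qtl_chrom, qtl_pos, qtl_effect, trait="PH")
    ]
    config = CrossConfig(seed=seed, heritability=heritability)
    return genome, qtls, config
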