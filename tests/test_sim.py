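"""Cross-simulator: meiosis, Mendelian segregation, pooling, sequencing."""

import numpy as np
import pytest

from bulkmap.sim import (CrossConfig, GenomeSpec, QTLSpec, assign_phenotypes,
                         make_parents, make_population, select_pools,
                         sequence_bulks, simulate_experiment, simulate_gamete,
                         Individual)
from bulkmap.vario import write_vcf

ONE_CHROM = GenomeSpec((("Chr1", 1_000_000),), marker_spacing=100_000)
TWO_CHROM = GenomeSpec((("Chr1", 1_000_000), ("Chr2", 1_000_000)),
                       marker_spacing=500_000)


class TestParents:
    def test_marker_grid_and_divergence(self):
        p1, p2 = make_parents(ONE_CHROM)
        assert ONE_CHROM.marker_positions("Chr1").size == 10
        assert (p1.haplotypes["Chr1"] == 0).all()
        assert (p2.haplotypes["Chr1"] == 1).all()

    def test_spacing_beyond_chromosome_errors(self):
        genome = GenomeSpec((("Chr1", 1000),), marker_spacing=5000)
        with pytest.raises(ValueError, match="zero markers"):
            make_parents(genome)

    def test_same_seed_identical(self):
        a = make_parents(ONE_CHROM, seed=7)
        b = make_parents(ONE_CHROM, seed=7)
        assert (a[0].haplotypes["Chr1"] == b[0].haplotypes["Chr1"]).all()


class TestGamete:
    def test_no_recombination_returns_intact_haplotype(self, rng):
        genome = GenomeSpec((("Chr1", 1_000_000),), marker_spacing=100_000,
                            cm_per_mb=0.0)
        p1, p2 = make_parents(genome)
        f1 = Individual({"Chr1": np.stack([p1.haplotypes["Chr1"][0],
                                           p2.haplotypes["Chr1"][0]])})
        for _ in range(20):
            g = simulate_gamete(f1, genome, rng)["Chr1"]
            assert (g == 0).all() or (g == 1).all()

    def test_homozygous_input_unchanged_by_crossovers(self, rng):
        genome = GenomeSpec((("Chr1", 1_000_000),), marker_spacing=100_000,
                            cm_per_mb=500.0)
        p1, _ = make_parents(genome)
        for _ in range(10):
            assert (simulate_gamete(p1, genome, rng)["Chr1"] == 0).all()

    def test_f1_gamete_allele_frequency_binomial(self, rng):
        genome = GenomeSpec((("Chr1", 100_000),), marker_spacing=100_000)
        p1, p2 = make_parents(genome)
        f1 = Individual({"Chr1": np.stack([p1.haplotypes["Chr1"][0],
                                           p2.haplotypes["Chr1"][0]])})
        freq = np.mean([simulate_gamete(f1, genome, rng)["Chr1"][0]
                        for _ in range(10_000)])
        assert abs(freq - 0.5) < 0.02

    def test_linkage_decay_monotone(self, rng):
        # dosage correlation between the first marker and progressively
        # distant markers must decrease on 10,000 gametes
        genome = GenomeSpec((("Chr1", 30_000_000),), marker_spacing=5_000_000,
                            cm_per_mb=4.0)
        p1, p2 = make_parents(genome)
        f1 = Individual({"Chr1": np.stack([p1.haplotypes["Chr1"][0],
                                           p2.haplotypes["Chr1"][0]])})
        gametes = np.array([simulate_gamete(f1, genome, rng)["Chr1"]
                            for _ in range(10_000)], dtype=float)
        corr = [np.corrcoef(gametes[:, 0], gametes[:, j])[0, 1]
                for j in range(1, gametes.shape[1])]
        assert all(np.diff(corr) < 0)


def _f3_genotype_probs():
    """Brute-force enumeration of two selfing generations at one locus."""
    # genotype index = alt dosage; selfing transition probabilities
    selfing = {0: {0: 1.0}, 2: {2: 1.0},
               1: {0: 0.25, 1: 0.5, 2: 0.25}}
    f2 = {0: 0.25, 1: 0.5, 2: 0.25}
    f3 = {0: 0.0, 1: 0.0, 2: 0.0}
    for g, p in f2.items():
        for g2, q in selfing[g].items():
            f3[g2] += p * q
    return f2, f3


class TestPopulation:
    def test_f2_heterozygote_fraction(self):
        cfg = CrossConfig(n_individuals=10_000, generation="F2", seed=3)
        pop = make_population(make_parents(TWO_CHROM), TWO_CHROM, cfg)
        het = np.mean([ind.dosage("Chr1", 0) == 1 for ind in pop])
        assert abs(het - 0.5) < 0.02

    def test_f3_genotype_frequencies_match_enumeration(self):
        _, f3 = _f3_genotype_probs()
        assert f3 == {0: 0.375, 1: 0.25, 2: 0.375}
        cfg = CrossConfig(n_individuals=10_000, generation="F3", seed=4)
        pop = make_population(make_parents(TWO_CHROM), TWO_CHROM, cfg)
        dos = np.array([ind.dosage("Chr2", 0) for ind in pop])
        for g, p in f3.items():
            sd = np.sqrt(p * (1 - p) / 10_000)
            assert abs(np.mean(dos == g) - p) < 3 * sd + 1e-9

    def test_fixed_seed_bit_identical(self):
        cfg = CrossConfig(n_individuals=50, seed=11)
        parents = make_parents(TWO_CHROM)
        a = make_population(parents, TWO_CHROM, cfg)
        b = make_population(parents, TWO_CHROM, cfg)
        for x, y in zip(a, b):
            for c in ("Chr1", "Chr2"):
                assert (x.haplotypes[c] == y.haplotypes[c]).all()

    def test_too_small_population_errors(self):
        with pytest.raises(ValueError):
            make_population(make_parents(TWO_CHROM), TWO_CHROM,
                            CrossConfig(n_individuals=1))


class TestPhenotypes:
    def test_zero_qtls_h0_pure_noise(self, rng):
        cfg = CrossConfig(n_individuals=200, seed=5)
        pop = make_population(make_parents(TWO_CHROM), TWO_CHROM, cfg)
        ph, _ = assign_phenotypes(pop, TWO_CHROM, [], 0.0, rng)
        assert abs(np.std(ph) - 1.0) < 0.2

    def test_full_heritability_three_phenotype_classes(self, rng):
        cfg = CrossConfig(n_individuals=500, generation="F2", seed=6)
        pop = make_population(make_parents(TWO_CHROM), TWO_CHROM, cfg)
        qtl = QTLSpec("Chr1", 500_000, additive_effect=2.0)
        ph, _ = assign_phenotypes(pop, TWO_CHROM, [qtl], 1.0, rng)
        assert len(np.unique(np.round(ph, 9))) == 3

    def test_f2_additive_variance_closed_form(self, rng):
        # var(a*(dosage-1)) = a^2/2 in an F2
        a = 1.7
        cfg = CrossConfig(n_individuals=10_000, generation="F2", seed=7)
        pop = make_population(make_parents(TWO_CHROM), TWO_CHROM, cfg)
        qtl = QTLSpec("Chr1", 500_000, additive_effect=a)
        ph, _ = assign_phenotypes(pop, TWO_CHROM, [qtl], 1.0, rng)
        assert abs(np.var(ph) - a**2 / 2) < 0.05 * a**2 / 2

    def test_full_heritability_without_qtls_errors(self, rng):
        cfg = CrossConfig(n_individuals=50, seed=8)
        pop = make_population(make_parents(TWO_CHROM), TWO_CHROM, cfg)
        with pytest.raises(ValueError):
            assign_phenotypes(pop, TWO_CHROM, [], 1.0, rng)

    def test_qtl_off_marker_errors(self, rng):
        cfg = CrossConfig(n_individuals=10, seed=9)
        pop = make_population(make_parents(TWO_CHROM), TWO_CHROM, cfg)
        with pytest.raises(ValueError, match="coincide"):
            assign_phenotypes(pop, TWO_CHROM,
                              [QTLSpec("Chr1", 123_456, 1.0)], 0.5, rng)


class TestPools:
    def test_design_pool_size(self):
        low, high = select_pools(np.random.default_rng(0).normal(size=299), 0.10)
        assert len(low) == len(high) == 30  # round(29.9) = 30

    def test_extreme_tails(self):
        low, high = select_pools(np.arange(1, 11, dtype=float), 0.2)
        assert list(low) == [0, 1] and list(high) == [8, 9]

    def test_tie_rule_first_last_by_index(self):
        low, high = select_pools(np.ones(10), 0.2)
        assert list(low) == [0, 1] and list(high) == [8, 9]

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            select_pools(np.arange(10.0), 0.6)


class TestSequencing:
    def _fixed_population(self, dosage, n=8):
        m = TWO_CHROM.marker_positions("Chr1").size
        hap = np.full((2, m), dosage // 2 + dosage % 2, dtype=np.uint8)
        hap[1] = dosage - hap[0]
        return [Individual({"Chr1": hap.copy(),
                            "Chr2": hap.copy()}) for _ in range(n)]

    def test_fixed_alt_bulk_error_free(self):
        pop = self._fixed_population(2)
        cfg = CrossConfig(n_individuals=8, seq_error_rate=0.0, seed=1)
        rng = np.random.default_rng(0)
        table = sequence_bulks(pop, TWO_CHROM, (np.arange(4), np.arange(4, 8)),
                               cfg, rng)
        for r in table:
            assert r.low_ad[0] == 0 and r.high_ad[0] == 0

    def test_half_frequency_binomial_mean(self):
        genome = GenomeSpec((("Chr1", 100_000_000),), marker_spacing=10_000)
        m = genome.marker_positions("Chr1").size
        assert m == 10_000
        het = np.zeros((2, m), dtype=np.uint8)
        het[1] = 1
        pop = [Individual({"Chr1": het.copy()}) for _ in range(8)]
        cfg = CrossConfig(n_individuals=8, bulk_depth_mean=50,
                          seq_error_rate=0.0, seed=1)
        table = sequence_bulks(pop, genome, (np.arange(4), np.arange(4, 8)),
                               cfg, np.random.default_rng(0))
        frac = np.mean([r.low_ad[1] / r.low_depth for r in table
                        if r.low_depth > 0])
        assert abs(frac - 0.5) < 0.01

    def test_empty_pool_errors(self):
        pop = self._fixed_population(2)
        cfg = CrossConfig(n_individuals=8, seed=1)
        with pytest.raises(ValueError, match="empty pool"):
            sequence_bulks(pop, TWO_CHROM, (np.array([], dtype=int),
                                            np.arange(4)), cfg,
                           np.random.default_rng(0))


class TestExperiment:
    def test_vcf_byte_determinism(self, tmp_path):
        genome = GenomeSpec((("Chr1", 2_000_000),), marker_spacing=200_000)
        qtls = [QTLSpec("Chr1", 1_000_000, 1.0)]
        cfg = CrossConfig(n_individuals=40, seed=42)
        for name in ("a.vcf", "b.vcf"):
            simulate_experiment(genome, qtls, cfg, vcf_path=tmp_path / name)
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_selection_signal_at_qtl(self):
        # with a strong QTL, the between-pool allele-frequency difference
        # at the QTL exceeds that at an unlinked marker (20 seeds average)
        genome = GenomeSpec((("Chr1", 500_000), ("Chr2", 500_000)),
                            marker_spacing=500_000)
        diffs_qtl, diffs_null = [], []
        for seed in range(20):
            cfg = CrossConfig(n_individuals=299, heritability=0.5, seed=seed)
            qtls = [QTLSpec("Chr1", 500_000, 1.0)]
            parents = make_parents(genome)
            pop = make_population(parents, genome, cfg)
            rng = np.random.default_rng(seed + 999)
            ph, _ = assign_phenotypes(pop, genome, qtls, 0.5, rng)
            low, high = select_pools(ph, 0.10)
            for chrom, sink in (("Chr1", diffs_qtl), ("Chr2", diffs_null)):
                dos = np.array([ind.dosage(chrom, 0) for ind in pop]) / 2.0
                sink.append(abs(dos[high].mean() - dos[low].mean()))
        assert np.mean(diffs_qtl) > np.mean(diffs_null)
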