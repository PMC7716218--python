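import math

import numpy as np
import pytest
from scipy import stats

from ewemap.bsa import F2_MUTANT, LER_POOL
from ewemap.genome import COL, LER
from ewemap.simulate import (
    MUTANT,
    NORMAL,
    Line,
    PoolSpec,
    Site,
    INDUCED,
    NATURAL,
    SimulationConfig,
    random_reference,
    simulate_ems_line,
    simulate_experiment,
    simulate_f2_population,
    simulate_pool_counts,
)


@pytest.fixture
def reference(small_genome):
    return random_reference(small_genome, seed=0)


class TestEmsLine:
    def test_transition_fraction_one_forces_signature(self, small_genome, reference):
        muts = simulate_ems_line(small_genome, reference, 10, 1.0, seed=1)
        assert len(muts) == 10
        assert all((m.ref, m.alt) in (("G", "A"), ("C", "T")) for m in muts if not m.is_causal)
        assert sum(m.is_causal for m in muts) == 1

    def test_transition_fraction_zero_excludes_signature(self, small_genome, reference):
        muts = simulate_ems_line(small_genome, reference, 10, 0.0, seed=1)
        non_causal = [m for m in muts if not m.is_causal]
        assert all((m.ref, m.alt) not in (("G", "A"), ("C", "T")) for m in non_causal)

    def test_positions_distinct_and_ref_matches_sequence(self, small_genome, reference):
        muts = simulate_ems_line(small_genome, reference, 50, 0.99, seed=3)
        positions = {(m.chrom, m.pos) for m in muts}
        assert len(positions) == 50
        assert all(reference[m.chrom][m.pos - 1] == m.ref for m in muts)

    def test_pooled_transition_fraction_matches_binomial_oracle(self, small_genome, reference):
        # Non-causal mutations are signature transitions i.i.d. Bernoulli(0.99);
        # the pooled fraction over 50 seeds must sit within 3 SE of 0.99.
        p, n_per, n_seeds = 0.99, 200, 50
        hits = total = 0
        for seed in range(n_seeds):
            muts = simulate_ems_line(small_genome, reference, n_per, p, seed=seed)
            non_causal = [m for m in muts if not m.is_causal]
            hits += sum((m.ref, m.alt) in (("G", "A"), ("C", "T")) for m in non_causal)
            total += len(non_causal)
        se = math.sqrt(p * (1 - p) / total)
        assert abs(hits / total - p) < 3 * se

    def test_too_many_mutations_rejected(self, small_genome, reference):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_ems_line(small_genome, reference, 3_000_000, 0.99, seed=0)

    def test_causal_site_can_be_pinned(self, small_genome, reference):
        muts = simulate_ems_line(
            small_genome, reference, 5, 1.0, seed=0, causal_site=("chr1", 100_450)
        )
        causal = next(m for m in muts if m.is_causal)
        assert (causal.chrom, causal.pos) == ("chr1", 100_450)


class TestF2Population:
    def test_zero_cm_chromosome_gives_single_segment_haplotypes(self, tiny_flat_genome):
        ref = random_reference(tiny_flat_genome, seed=0)
        muts = simulate_ems_line(tiny_flat_genome, ref, 1, 1.0, seed=0)
        plants = simulate_f2_population(tiny_flat_genome, muts[0], 50, seed=2)
        for p in plants:
            for hap in p.haplotypes["chrZ"]:
                assert len(hap.starts) == 1

    def test_segments_tile_chromosome(self, small_genome, reference):
        muts = simulate_ems_line(small_genome, reference, 1, 1.0, seed=0)
        plants = simulate_f2_population(small_genome, muts[0], 200, seed=5)
        length = small_genome.chromosome("chr1").length_bp
        for p in plants[:50]:
            for hap in p.haplotypes["chr1"]:
                segs = hap.segments(length)
                assert segs[0][0] == 1 and segs[-1][1] == length
                covered = sum(end - start + 1 for start, end, _ in segs)
                assert covered == length
                for (s1, e1, _), (s2, _, _) in zip(segs, segs[1:]):
                    assert s2 == e1 + 1
                assert hap.origin_at(1) in (COL, LER)
                assert hap.origin_at(length) in (COL, LER)

    def test_mutant_fraction_matches_recessive_expectation(self, small_genome, reference):
        muts = simulate_ems_line(small_genome, reference, 1, 1.0, seed=0)
        plants = simulate_f2_population(small_genome, muts[0], 4000, seed=7)
        frac = sum(p.phenotype == MUTANT for p in plants) / len(plants)
        se = math.sqrt(0.25 * 0.75 / 4000)
        assert abs(frac - 0.25) < 3 * se

    def test_phenotype_follows_recessive_rule(self, small_genome, reference):
        muts = simulate_ems_line(small_genome, reference, 1, 1.0, seed=0)
        causal = muts[0]
        plants = simulate_f2_population(small_genome, causal, 300, seed=9)
        for p in plants:
            g = p.genotype_at(causal.chrom, causal.pos)
            assert (p.phenotype == MUTANT) == (g == (COL, COL))

    def test_linked_marker_ler_frequency_in_mutants_equals_r(self):
        # Marker at recombination fraction r = 0.1 from the causal locus:
        # in the recessive-selected bulk every gamete carries the causal
        # allele, so the marker shows the Ler allele with probability r.
        from ewemap.genome import ChromosomeModel, GenomeModel
        from ewemap.simulate import InducedMutation

        r = 0.1
        d_cm = -50.0 * math.log(1 - 2 * r)  # Haldane inverse
        length_cm = 40.0
        chrom = ChromosomeModel("c", 4_000_000, length_cm)
        genome = GenomeModel([chrom])
        causal = InducedMutation("c", int(chrom.cm_to_bp(15.0)), "G", "A", True)
        marker_bp = int(chrom.cm_to_bp(15.0 + d_cm))
        plants = simulate_f2_population(genome, causal, 2500, seed=11)
        mutants = [p for p in plants if p.phenotype == MUTANT]
        ler = sum(
            (h.origin_at(marker_bp) == LER)
            for p in mutants
            for h in p.haplotypes["c"]
        )
        n = 2 * len(mutants)
        se = math.sqrt(r * (1 - r) / n)
        assert abs(ler / n - r) < 3 * se

    def test_unlinked_marker_segregates_1_2_1_in_full_f2(self, small_genome, reference):
        # Genotype classes at a marker far from the causal locus fit 1:2:1
        # among ALL plants (selection only acts at the causal locus).
        muts = simulate_ems_line(
            small_genome, reference, 1, 1.0, seed=0, causal_site=("chr1", 50_000)
        )
        plants = simulate_f2_population(small_genome, muts[0], 2000, seed=13)
        counts = {0: 0, 1: 0, 2: 0}
        for p in plants:
            g = p.genotype_at("chr1", 1_950_000)
            counts[sum(o == LER for o in g)] += 1
        chi2 = stats.chisquare(
            [counts[0], counts[1], counts[2]],
            [len(plants) / 4, len(plants) / 2, len(plants) / 4],
        )
        assert chi2.pvalue > 0.001


class TestPoolCounts:
    def test_fixed_alt_pool_without_error_is_all_alt(self):
        sites = [Site("c", 100, "G", "A", INDUCED)]
        pools = [PoolSpec("ORIG_MUTANT", [Line("m", COL, True)], 30.0)]
        recs = simulate_pool_counts(sites, pools, error_rate=0.0, seed=0)
        ref_d, alt_d = recs[0].depths["ORIG_MUTANT"]
        assert ref_d == 0 and alt_d > 0

    def test_heterozygous_single_plant_pool_is_half_alt(self, small_genome, reference):
        muts = simulate_ems_line(small_genome, reference, 1, 1.0, seed=0)
        causal = muts[0]
        plants = simulate_f2_population(small_genome, causal, 50, seed=1)
        het = next(
            p for p in plants
            if sorted(p.genotype_at(causal.chrom, causal.pos)) == [COL, LER]
        )
        sites = [Site(causal.chrom, causal.pos, causal.ref, causal.alt, INDUCED)]
        pools = [PoolSpec(F2_MUTANT if het.phenotype == MUTANT else "F2_NORMAL", [het], 10_000.0)]
        recs = simulate_pool_counts(sites, pools, error_rate=0.0, seed=2)
        ref_d, alt_d = list(recs[0].depths.values())[0]
        frac = alt_d / (ref_d + alt_d)
        se = math.sqrt(0.25 / (ref_d + alt_d))
        assert abs(frac - 0.5) < 3 * se

    def test_mean_depth_matches_poisson_oracle(self):
        sites = [Site("c", i + 1, "G", "A", NATURAL) for i in range(500)]
        pools = [PoolSpec(LER_POOL, [Line("ler", LER, False)], 50.0)]
        recs = simulate_pool_counts(sites, pools, error_rate=0.0, seed=3)
        depths = [sum(r.depths[LER_POOL]) for r in recs]
        se = math.sqrt(50.0 / len(depths))
        assert abs(np.mean(depths) - 50.0) < 3 * se

    def test_empty_pool_rejected(self):
        sites = [Site("c", 1, "G", "A", INDUCED)]
        with pytest.raises(ValueError, match="empty"):
            simulate_pool_counts(sites, [PoolSpec(LER_POOL, [], 10.0)], seed=0)

    def test_f2_mutant_pool_rejects_normal_plants(self, small_genome, reference):
        muts = simulate_ems_line(small_genome, reference, 1, 1.0, seed=0)
        plants = simulate_f2_population(small_genome, muts[0], 100, seed=1)
        normals = [p for p in plants if p.phenotype == NORMAL]
        with pytest.raises(ValueError, match="MUTANT"):
            PoolSpec(F2_MUTANT, normals[:3], 50.0)


class TestReproducibility:
    def test_same_seed_is_bit_identical(self):
        cfg = SimulationConfig(n_f2_plants=60, bulk_size=10, n_mutations=20)
        a = simulate_experiment(cfg, seed=42)
        b = simulate_experiment(cfg, seed=42)
        assert a.mutations == b.mutations
        assert a.reference == b.reference
        assert [p.phenotype for p in a.plants] == [p.phenotype for p in b.plants]
        assert a.plants[0].haplotypes["chr1"] == b.plants[0].haplotypes["chr1"]
        assert a.snp_records == b.snp_records

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(n_f2_plants=60, bulk_size=10, n_mutations=20)
        a = simulate_experiment(cfg, seed=1)
        b = simulate_experiment(cfg, seed=2)
        assert a.mutations != b.mutations
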