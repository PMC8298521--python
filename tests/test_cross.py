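"""Haploid cross simulator: meiosis model, segregation, bulks, pooled depths."""

import math

import numpy as np
import pytest

from mossmap.cross import (GD, VX, CrossConfig, GeneticMap, make_bulk,
                           genotype_table, simulate_cross, simulate_meiosis,
                           simulate_pool_depths)
from mossmap.genome import Marker, MarkerMap
from mossmap.linkage import haldane_r
from mossmap.scenario import bsa_scenario


def identity_map(cM):
    """1 cM == 10 kb, anchored at 0 (linear toy map)."""
    return np.asarray(cM, dtype=float) * 10_000


class TestSimulateMeiosis:
    def test_zero_genetic_length_is_a_single_segment(self, rng):
        bp, first = simulate_meiosis(0.0, 1_000_000, identity_map, rng)
        assert len(bp) == 0
        assert first in {GD, VX}

    def test_marker_compared_with_itself_never_discordant(self, rng):
        from mossmap.cross import Haplotype
        for _ in range(200):
            bp, first = simulate_meiosis(100.0, 1_000_000, identity_map, rng)
            hap = Haplotype({"c": (bp, first)})
            scalar = hap.origin_at("c", 500_000)
            vector = hap.origins_at("c", np.array([500_000.0]))[0]
            assert scalar == vector

    def test_discordance_matches_haldane_at_10cM(self, rng):
        """Over 10,000 meioses the discordant fraction between loci 10 cM
        apart sits within 3 SE of the Haldane closed form 0.5*(1-e^-0.2)."""
        n = 10_000
        pos_a, pos_b = 400_000, 500_000  # 40 and 50 cM under the toy map
        disc = 0
        for _ in range(n):
            bp, first = simulate_meiosis(100.0, 1_000_000, identity_map, rng)
            fa = np.searchsorted(bp, pos_a, side="right") % 2
            fb = np.searchsorted(bp, pos_b, side="right") % 2
            disc += fa != fb
        expected = haldane_r(10.0)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(disc / n - expected) < 3 * se

    def test_negative_length_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_meiosis(-1.0, 100, identity_map, rng)


class TestSimulateCross:
    def test_phenotype_equals_causal_origin_at_full_penetrance(self, small_genome,
                                                               linear_markers):
        cfg = CrossConfig(genome=small_genome, markers=linear_markers,
                          causal_locus=("chr1", 2_500_000), n_progeny=60,
                          n_bulk=10, seed=7)
        for seg in simulate_cross(cfg):
            origin = seg.haplotype.origin_at("chr1", 2_500_000)
            assert seg.phenotype == ("down" if origin == GD else "up")

    def test_one_to_one_segregation(self):
        cfg = bsa_scenario(seed=11, n_progeny=1000, n_bulk=48)
        segs = simulate_cross(cfg)
        n_down = sum(s.phenotype == "down" for s in segs)
        # 99% binomial bounds around 500/1000
        lo = 500 - 2.5758 * math.sqrt(1000 * 0.25)
        hi = 500 + 2.5758 * math.sqrt(1000 * 0.25)
        assert lo <= n_down <= hi

    def test_same_seed_reproduces_everything(self, small_genome, linear_markers):
        cfg = CrossConfig(genome=small_genome, markers=linear_markers,
                          causal_locus=("chr1", 2_500_000), n_progeny=25,
                          n_bulk=5, seed=99)
        a = simulate_cross(cfg)
        b = simulate_cross(cfg)
        assert [s.phenotype for s in a] == [s.phenotype for s in b]
        for x, y in zip(a, b):
            for chrom in small_genome.names:
                bx, fx = x.haplotype.segments[chrom]
                by, fy = y.haplotype.segments[chrom]
                assert fx == fy and np.array_equal(bx, by)

    def test_segments_tile_chromosome(self, small_genome, linear_markers):
        cfg = CrossConfig(genome=small_genome, markers=linear_markers,
                          causal_locus=("chr1", 2_500_000), n_progeny=40,
                          n_bulk=5, seed=3)
        for seg in simulate_cross(cfg):
            for chrom in small_genome:
                bp, _ = seg.haplotype.segments[chrom.name]
                assert np.all(np.diff(bp) > 0)  # strictly increasing: no empty segment
                assert np.all((bp > 1) & (bp <= chrom.length))

    def test_undetermined_rate_and_penetrance_validation(self, small_genome,
                                                         linear_markers):
        with pytest.raises(ValueError):
            CrossConfig(genome=small_genome, markers=linear_markers,
                        causal_locus=("chr1", 10), n_progeny=5, n_bulk=10)
        with pytest.raises(ValueError):
            CrossConfig(genome=small_genome, markers=linear_markers,
                        causal_locus=("chr9", 10), n_progeny=50, n_bulk=10)


class TestMakeBulk:
    def _segregants(self, n_down, n_up, n_undet=0):
        cfg = bsa_scenario(seed=5, n_progeny=200, n_bulk=10)
        segs = simulate_cross(cfg)
        down = [s for s in segs if s.phenotype == "down"][:n_down]
        up = [s for s in segs if s.phenotype == "up"][:n_up]
        return down + up

    def test_filter_and_truncate(self):
        segs = self._segregants(52, 48)
        bulk = make_bulk(segs, "down", 48)
        assert len(bulk) == 48
        assert all(s.phenotype == "down" for s in bulk)

    def test_insufficient_reports_available_count(self):
        segs = self._segregants(40, 60)
        with pytest.raises(ValueError, match="40 available"):
            make_bulk(segs, "down", 48)

    def test_bulk_and_complement_partition_input(self):
        segs = self._segregants(52, 48)
        bulk = make_bulk(segs, "down", 48)
        ids = {s.id for s in bulk}
        complement = [s for s in segs if s.id not in ids]
        assert len(bulk) + len(complement) == len(segs)

    def test_undetermined_never_bulked(self):
        with pytest.raises(ValueError):
            make_bulk([], "undetermined", 1)


class TestPoolDepths:
    def test_no_error_no_vx_templates(self, small_genome, linear_markers, rng):
        cfg = CrossConfig(genome=small_genome, markers=linear_markers,
                          causal_locus=("chr1", 2_500_000), n_progeny=120,
                          n_bulk=30, seed=2, error_rate=0.0)
        bulk = make_bulk(simulate_cross(cfg), "down", 30)
        depths = simulate_pool_depths(bulk, linear_markers, 50, 0.0, rng)
        causal = depths[(depths.chrom == "chr1") & (depths.pos_bp == 2_500_000)]
        assert int(causal.vx_depth.iloc[0]) == 0

    def test_mean_depth_matches_poisson_coverage(self, rng):
        cfg = bsa_scenario(seed=8)
        bulk = make_bulk(simulate_cross(cfg), "down", 48)
        depths = simulate_pool_depths(bulk, cfg.markers, 50, 0.01, rng)
        total = depths.gd_depth + depths.vx_depth
        se = math.sqrt(50 / len(total))
        assert abs(total.mean() - 50) < 3 * se

    def test_unlinked_marker_fraction_near_half_over_replicate_pools(self):
        """Law of total expectation: at a marker assorting independently of
        the selected phenotype the expected Gd read fraction is 0.5."""
        fractions = []
        for rep in range(200):
            cfg = bsa_scenario(seed=300 + rep, n_progeny=64, n_bulk=16,
                               n_markers=4, chrom_length=100_000,
                               causal_pos=50_000, total_cM=0.0)
            segs = simulate_cross(cfg)
            down = [s for s in segs if s.phenotype == "down"]
            if len(down) < 16:
                continue
            bulk = down[:16]
            rng = np.random.default_rng(900 + rep)
            # markers on a 0 cM chromosome cosegregate with the causal locus;
            # use an independent second chromosome instead
            from mossmap.genome import Chromosome, ToyGenome
            from mossmap.genome import Marker as M
            genome2 = ToyGenome((Chromosome("chrU", 100_000),))
            mk = MarkerMap((M("chrU", 50_000, 0.0, "u1", "A", "C"),))
            # give each bulk member an independent origin on chrU
            for s in bulk:
                coin = GD if rng.random() < 0.5 else VX
                s.haplotype.segments["chrU"] = (np.empty(0), coin)
            d = simulate_pool_depths(bulk, mk, 50, 0.0, rng)
            tot = int(d.gd_depth.iloc[0] + d.vx_depth.iloc[0])
            if tot:
                fractions.append(int(d.gd_depth.iloc[0]) / tot)
        mean = float(np.mean(fractions))
        se = float(np.std(fractions) / math.sqrt(len(fractions)))
        assert abs(mean - 0.5) < 4 * max(se, 1e-3)

    def test_causal_marker_fraction_is_one_minus_error(self):
        """Observed Gd fraction at the causal marker ~ 1 - error_rate."""
        vals = []
        for rep in range(30):
            cfg = bsa_scenario(seed=40 + rep, error_rate=0.05)
            bulk = make_bulk(simulate_cross(cfg), "down", 48)
            rng = np.random.default_rng(140 + rep)
            d = simulate_pool_depths(bulk, cfg.markers, 50, 0.05, rng)
            causal = d[d.pos_bp == 10_000_000]
            vals.append(float(causal.gd_depth.iloc[0]
                              / (causal.gd_depth.iloc[0] + causal.vx_depth.iloc[0])))
        assert abs(np.mean(vals) - 0.95) < 0.02

    def test_empty_bulk_rejected(self, linear_markers, rng):
        with pytest.raises(ValueError):
            simulate_pool_depths([], linear_markers, 50, 0.01, rng)


class TestGenotypeTable:
    def test_calls_match_haplotypes(self, small_genome, linear_markers):
        cfg = CrossConfig(genome=small_genome, markers=linear_markers,
                          causal_locus=("chr1", 2_500_000), n_progeny=10,
                          n_bulk=2, seed=4)
        segs = simulate_cross(cfg)
        table = genotype_table(segs, linear_markers)
        m = linear_markers.markers[3]
        for seg, call in zip(segs, table[m.id]):
            assert call == seg.haplotype.origin_at(m.chrom, m.pos_bp)

    def test_recombinant_fraction_monotone_in_genetic_distance(self):
        """Discordance with the causal locus rises with map distance along a
        marker ladder (averaged over meioses)."""
        cfg = bsa_scenario(seed=21, n_progeny=500, n_bulk=48)
        segs = simulate_cross(cfg)
        causal = ("chr1", 10_000_000)
        ladder_bp = [10_000_000, 11_000_000, 13_000_000, 16_000_000]
        fracs = []
        for pos in ladder_bp:
            disc = sum(
                s.haplotype.origin_at("chr1", pos)
                != s.haplotype.origin_at(*causal) for s in segs)
            fracs.append(disc / len(segs))
        assert fracs == sorted(fracs)
        assert fracs[0] == 0.0
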