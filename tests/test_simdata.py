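"""Simulator ground truth: construction, determinism, and distributional laws."""

import numpy as np
import pytest

from spacerscan._seq import encode, kmer_codes, revcomp
from spacerscan.simdata import (SimConfig, evolve_pair, simulate_ancestor,
                                simulate_metagenome, simulate_phage_pool)


class TestAncestor:
    def test_planted_array_structure(self):
        cfg = SimConfig(genome_length=50_000, n_initial_spacers=3, seed=1)
        g = simulate_ancestor(cfg)
        arr = g.arrays[0]
        assert len(g.seq) == 50_000 + arr.footprint
        assert len(arr.spacers) == 3
        # repeat(+spacer+repeat)x3 -> 4 repeat copies
        assert g.seq.count(arr.repeat) == 4

    def test_gc_zero_background_is_at_only(self):
        cfg = SimConfig(genome_length=20_000, gc=0.0, n_initial_spacers=3, seed=2)
        g = simulate_ancestor(cfg)
        assert set(g.background) <= {"A", "T"}

    def test_determinism(self):
        cfg = SimConfig(genome_length=20_000, n_initial_spacers=3, seed=3)
        assert simulate_ancestor(cfg).seq == simulate_ancestor(cfg).seq

    def test_too_small_genome_rejected(self):
        cfg = SimConfig(genome_length=100, n_initial_spacers=10, seed=1)
        with pytest.raises(ValueError, match="too small"):
            simulate_ancestor(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(gc=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(mu=-1).validate()
        with pytest.raises(ValueError):
            SimConfig(repeat_length=10).validate()


class TestPhagePool:
    def test_votu_grouping(self):
        cfg = SimConfig(n_phages=6, phages_per_votu=2, phage_length=2_000, seed=4)
        pool = simulate_phage_pool(cfg)
        votus = {}
        for p in pool:
            votus.setdefault(p.votu, []).append(p.id)
        assert len(pool) == 6
        assert sorted(len(v) for v in votus.values()) == [2, 2, 2]

    def test_single_phage_single_votu(self):
        cfg = SimConfig(n_phages=1, phage_length=2_000, seed=5)
        pool = simulate_phage_pool(cfg)
        assert len(pool) == 1
        assert pool[0].votu == "vOTU_000"

    def test_pools_from_different_seeds_share_no_30mers(self):
        pools = []
        for seed in (6, 7):
            cfg = SimConfig(n_phages=2, phage_length=20_000, seed=seed)
            pools.append(simulate_phage_pool(cfg))
        kmers = []
        for pool in pools:
            ks = set()
            for p in pool:
                ks.update(kmer_codes(encode(p.seq), 30).tolist())
            kmers.append(ks)
        assert not (kmers[0] & kmers[1])


class TestEvolvePair:
    def test_null_process_is_identity(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "mu": 0.0, "rho": 0.0})
        anc = simulate_ancestor(cfg)
        pool = simulate_phage_pool(cfg)
        a, b, truth = evolve_pair(anc, cfg, pool)
        assert a.seq == b.seq == anc.seq
        assert all(not v for v in truth.snv_positions.values())
        assert all(not v for v in truth.acquisitions.values())

    def test_snv_count_is_poisson_with_stated_mean(self):
        # mean mu*G*L_mutable; 100 replicates within 3 s.e. of the mean
        cfg = SimConfig(genome_length=100_000, mu=2e-8, rho=0.0,
                        generations=50_000, n_initial_spacers=3, seed=8)
        anc = simulate_ancestor(cfg)
        pool = simulate_phage_pool(cfg)
        mean_target = cfg.mu * cfg.generations * len(anc.background)
        rng = cfg.rng()
        counts = []
        for _ in range(50):
            _, _, truth = evolve_pair(anc, cfg, pool, rng)
            counts.extend(len(v) for v in truth.snv_positions.values())
        counts = np.array(counts)
        se = np.sqrt(mean_target / len(counts))
        assert abs(counts.mean() - mean_target) < 3 * se

    def test_acquisitions_at_leader_end_in_order(self):
        cfg = SimConfig(genome_length=30_000, mu=0.0, rho=2e-5, loss=0.0,
                        generations=500_000, n_initial_spacers=4, seed=9)
        anc = simulate_ancestor(cfg)
        pool = simulate_phage_pool(cfg)
        a, _, truth = evolve_pair(anc, cfg, pool)
        acquired = [acq.spacer for acq in truth.acquisitions[a.id]]
        n = len(acquired)
        # newest first at the leader end, then the ancestral spacers
        assert a.arrays[0].spacers[:n] == acquired[::-1]
        assert a.arrays[0].spacers[n:] == anc.arrays[0].spacers

    def test_acquired_spacers_found_in_source_phage(self):
        cfg = SimConfig(genome_length=30_000, rho=3e-5, n_initial_spacers=4, seed=10)
        anc = simulate_ancestor(cfg)
        pool = simulate_phage_pool(cfg)
        _, _, truth = evolve_pair(anc, cfg, pool)
        by_id = {p.id: p.seq for p in pool}
        acqs = [a for v in truth.acquisitions.values() for a in v]
        assert acqs, "expected at least one acquisition at these rates"
        for acq in acqs:
            src = by_id[acq.phage_id]
            assert acq.spacer in src or revcomp(acq.spacer) in src

    def test_empty_phage_pool_rejected(self, small_config):
        anc = simulate_ancestor(small_config)
        with pytest.raises(ValueError, match="phage pool"):
            evolve_pair(anc, small_config, [])

    def test_conserved_background_outside_snvs(self, small_config):
        anc = simulate_ancestor(small_config)
        pool = simulate_phage_pool(small_config)
        a, b, truth = evolve_pair(anc, small_config, pool)
        # with whole-array shielding, backgrounds align position-for-position
        bg_a, bg_b = np.frombuffer(a.background.encode(), dtype=np.uint8), \
            np.frombuffer(b.background.encode(), dtype=np.uint8)
        diff = int((bg_a != bg_b).sum())
        total_snvs = sum(len(v) for v in truth.snv_positions.values())
        assert diff <= total_snvs


class TestMetagenome:
    def test_exact_read_count(self, small_genome):
        reads, origins = simulate_metagenome([("g", small_genome.seq)], [1.0],
                                             1_000, seed=0)
        assert len(reads) == 1_000
        assert len(origins) == 1_000

    def test_origin_proportions_follow_abundance(self, rng):
        from spacerscan._seq import random_seq
        s1, s2 = random_seq(rng, 10_000), random_seq(rng, 10_000)
        reads, origins = simulate_metagenome([("a", s1), ("b", s2)], [3, 1],
                                             20_000, seed=1)
        n_a = int((origins["source"] == "a").sum())
        se = np.sqrt(20_000 * 0.75 * 0.25)
        assert abs(n_a - 15_000) < 3 * se

    def test_error_free_reads_are_exact_substrings(self, small_genome):
        reads, origins = simulate_metagenome([("g", small_genome.seq)], [1.0],
                                             500, error_rate=0.0, seed=2)
        for i, (rid, row) in enumerate(origins.iterrows()):
            seq = reads.sequence(i)
            frag = small_genome.seq[row["pos"]:row["pos"] + 150]
            assert seq == (frag if row["strand"] == "+" else revcomp(frag))

    def test_short_source_rejected(self):
        with pytest.raises(ValueError, match="shorter than read_len"):
            simulate_metagenome([("tiny", "ACGT" * 10)], [1.0], 10, seed=0)

    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError):
            simulate_metagenome([("a", "A" * 500)], [0.0], 10, seed=0)
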