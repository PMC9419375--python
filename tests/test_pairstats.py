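"""Pairwise ANI, SNV estimation and the turnover estimator."""

import math

import numpy as np
import pytest

from spacerscan._seq import random_seq
from spacerscan.pairstats import (estimate_snvs, fragment_ani, pair_table,
                                  shared_spacer_fraction, spacers_per_generation)
from spacerscan.simdata import SimConfig, evolve_pair, simulate_ancestor, simulate_phage_pool


class TestFragmentANI:
    def test_identical_genomes(self, rng):
        g = random_seq(rng, 20_000)
        ani, n = fragment_ani(g, g)
        assert ani == 100.0
        assert n == 2 * (20_000 // 1_000)

    def test_known_divergence_recovered(self, rng):
        from spacerscan._seq import decode, encode
        g = random_seq(rng, 50_000)
        arr = encode(g).copy()
        pos = rng.choice(arr.size, 500, replace=False)  # 1% divergence
        arr[pos] = (arr[pos] + rng.integers(1, 4, size=500)) % 4
        ani, n = fragment_ani(g, decode(arr))
        assert 98.8 <= ani <= 99.2
        assert n == 100

    def test_unrelated_genomes_flagged(self, rng):
        a, b = random_seq(rng, 100_000), random_seq(rng, 100_000)
        ani, n = fragment_ani(a, b)
        assert n == 0 and math.isnan(ani)

    def test_symmetry_within_tolerance(self, rng):
        cfg = SimConfig(genome_length=40_000, seed=41)
        anc = simulate_ancestor(cfg)
        a, b, _ = evolve_pair(anc, cfg, simulate_phage_pool(cfg))
        ani_ab, _ = fragment_ani(a.seq, b.seq)
        ani_ba, _ = fragment_ani(b.seq, a.seq)
        assert abs(ani_ab - ani_ba) <= 0.1

    def test_too_short_genomes_rejected(self):
        with pytest.raises(ValueError):
            fragment_ani("ACGT" * 10, "ACGT" * 10)


class TestEstimateSnvs:
    def test_formula(self):
        assert estimate_snvs(99.9, 500) == pytest.approx(500.0)

    def test_identical_genomes_zero(self):
        assert estimate_snvs(100.0, 300) == 0.0

    def test_undefined_ani_rejected(self):
        with pytest.raises(ValueError):
            estimate_snvs(float("nan"), 10)

    def test_recovers_truth_on_simulated_pairs(self):
        ratios = []
        for seed in range(5):
            cfg = SimConfig(genome_length=100_000, seed=50 + seed)
            rng = cfg.rng()
            anc = simulate_ancestor(cfg, rng)
            a, b, truth = evolve_pair(anc, cfg, simulate_phage_pool(cfg, rng), rng)
            ani, n = fragment_ani(a.seq, b.seq)
            est = estimate_snvs(ani, n / 2)
            true = sum(len(v) for v in truth.snv_positions.values())
            ratios.append(est / true)
        assert abs(np.median(ratios) - 1) < 0.15


class TestSharedSpacers:
    def test_partial_overlap(self):
        out = shared_spacer_fraction(["AAACCCGGGTTTACG", "CCCGGGTTTACGAAA", "GGGTTTACGAAACCC"],
                                     ["CCCGGGTTTACGAAA", "GGGTTTACGAAACCC", "TTTACGAAACCCGGG"])
        assert out["shared"] == 2
        assert out["union"] == 4
        assert out["fraction"] == 0.5
        assert out["unique"] == 2

    def test_identical_sets(self, rng):
        sp = [random_seq(rng, 33) for _ in range(4)]
        out = shared_spacer_fraction(sp, list(sp))
        assert out["fraction"] == 1.0 and out["unique"] == 0

    def test_disjoint_sets(self, rng):
        a = [random_seq(rng, 33) for _ in range(3)]
        b = [random_seq(rng, 33) for _ in range(2)]
        out = shared_spacer_fraction(a, b)
        assert out["fraction"] == 0.0 and out["unique"] == 5

    def test_total_denominator_option(self, rng):
        a = [random_seq(rng, 33) for _ in range(3)]
        out = shared_spacer_fraction(a, list(a), denominator="total")
        assert out["fraction"] == 0.5  # 3 shared over |A|+|B| = 6


class TestTurnover:
    def test_worked_example(self):
        # one spacer per 1355 SNVs, mu=8.9e-11, 2.3 Mb aligned, 1e7 cells
        rate = spacers_per_generation(1355.0, 1, mu=8.9e-11,
                                      aligned_len=2.3e6, community_size=1e7)
        assert rate == pytest.approx(1e7 * 8.9e-11 * 2.3e6 / 1355)
        assert rate == pytest.approx(1.51, abs=0.01)

    def test_linearity_in_unique_spacers(self):
        r1 = spacers_per_generation(1000.0, 5, mu=1e-10, aligned_len=1e6)
        r2 = spacers_per_generation(1000.0, 10, mu=1e-10, aligned_len=1e6)
        assert r2 == pytest.approx(2 * r1)

    def test_no_unique_spacers_flagged(self):
        assert math.isnan(spacers_per_generation(1000.0, 0, aligned_len=1e6))


class TestPairTable:
    def test_pair_count_is_combinatorial(self, rng):
        genomes = {f"g{i}": random_seq(rng, 5_000) for i in range(4)}
        spacers = {g: [random_seq(rng, 33)] for g in genomes}
        table, _ = pair_table(genomes, spacers)
        assert len(table) == 6

    def test_clonal_replicates_degenerate_regression(self, rng):
        g = random_seq(rng, 5_000)
        sp = [random_seq(rng, 33) for _ in range(3)]
        genomes = {f"g{i}": g for i in range(3)}
        spacers = {k: list(sp) for k in genomes}
        table, summary = pair_table(genomes, spacers)
        assert (table["shared_fraction"] == 1.0).all()
        assert summary["regression"].get("degenerate")

    def test_shared_fraction_declines_with_divergence(self):
        # star of lineages at staggered divergence times
        genomes, spacers = {}, {}
        for j, G in enumerate((150_000, 450_000, 1_350_000)):
            cfg = SimConfig(genome_length=60_000, generations=G, seed=61)
            rng = cfg.rng()
            anc = simulate_ancestor(cfg, rng)
            a, b, _ = evolve_pair(anc, cfg, simulate_phage_pool(cfg, rng), rng,
                                  ids=(f"a{j}", f"b{j}"))
            from spacerscan.array_detect import detect_arrays
            for g in (a, b):
                genomes[g.id] = g.seq
                spacers[g.id] = [s for arr in detect_arrays(g.seq)
                                 for s in arr.spacers]
        fracs, anis = [], []
        for j in range(3):
            ani, n = fragment_ani(genomes[f"a{j}"], genomes[f"b{j}"])
            sh = shared_spacer_fraction(spacers[f"a{j}"], spacers[f"b{j}"])
            anis.append(ani)
            fracs.append(sh["fraction"])
        assert anis[0] > anis[1] > anis[2]
        assert fracs[0] >= fracs[1] >= fracs[2]
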