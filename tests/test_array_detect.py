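"""Array detection: planted recovery, filters, and structural invariants."""

import numpy as np

from spacerscan._seq import random_seq
from spacerscan.array_detect import (Candidate, SpacerArray, build_arrays,
                                     detect_arrays, filter_arrays,
                                     find_repeat_candidates, spacer_table)
from spacerscan.simdata import SimConfig, simulate_ancestor


def _plant(rng, repeat, spacers, flank=3_000):
    left = random_seq(rng, flank)
    right = random_seq(rng, flank)
    array = repeat + "".join(s + repeat for s in spacers)
    return left + array + right, flank


class TestFindCandidates:
    def test_planted_four_copy_array_found_at_planted_positions(self, rng):
        repeat = random_seq(rng, 28)
        spacers = [random_seq(rng, 32) for _ in range(3)]
        seq, start = _plant(rng, repeat, spacers)
        cands = find_repeat_candidates(seq)
        assert len(cands) >= 1
        best = max(cands, key=lambda c: c.n_copies)
        assert best.n_copies == 4
        assert best.rep_len == 28
        expected = [start]
        for s in spacers:
            expected.append(expected[-1] + 28 + len(s))
        assert list(best.starts) == expected

    def test_two_arrays_with_distinct_repeats_give_disjoint_sets(self, rng):
        r1, r2 = random_seq(rng, 30), random_seq(rng, 36)
        a1 = r1 + "".join(s + r1 for s in (random_seq(rng, 33) for _ in range(3)))
        a2 = r2 + "".join(s + r2 for s in (random_seq(rng, 30) for _ in range(4)))
        seq = random_seq(rng, 2_000) + a1 + random_seq(rng, 2_000) + a2 \
            + random_seq(rng, 2_000)
        arrays = build_arrays(find_repeat_candidates(seq), seq)
        assert len(arrays) == 2
        assert arrays[0].end <= arrays[1].start

    def test_random_sequence_yields_no_candidates(self):
        hits = 0
        for seed in range(10):
            seq = random_seq(np.random.default_rng(seed), 50_000)
            if build_arrays(find_repeat_candidates(seq), seq):
                hits += 1
        assert hits == 0


class TestBuildArrays:
    def test_spacers_recovered_in_genomic_order(self, rng):
        repeat = random_seq(rng, 36)
        spacers = [random_seq(rng, L) for L in (30, 35, 40)]
        seq, _ = _plant(rng, repeat, spacers)
        arrays = build_arrays(find_repeat_candidates(seq), seq)
        assert len(arrays) == 1
        assert arrays[0].spacers == spacers
        assert arrays[0].consensus_repeat == repeat

    def test_reconstruction_matches_genome_slice(self, small_genome):
        arrays = detect_arrays(small_genome.seq, apply_filter=False)
        assert arrays
        for arr in arrays:
            assert arr.reconstruct() == small_genome.seq[arr.start:arr.end]

    def test_consensus_is_columnwise_majority(self, rng):
        repeat = random_seq(rng, 30)
        spacers = [random_seq(rng, 33) for _ in range(3)]
        seq, start = _plant(rng, repeat, spacers)
        # mutate one column of one copy; majority should still win
        pos = start + 30 + 33 + 10  # column 10 of the second copy
        old = seq[pos]
        new = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
        seq = seq[:pos] + new + seq[pos + 1:]
        starts = [start]
        for s in spacers:
            starts.append(starts[-1] + 30 + len(s))
        arrays = build_arrays([Candidate(tuple(starts), 30)], seq)
        assert arrays and arrays[0].consensus_repeat == repeat

    def test_two_copies_do_not_make_an_array(self, rng):
        repeat = random_seq(rng, 30)
        seq, start = _plant(rng, repeat, [random_seq(rng, 33)])
        cand = Candidate((start, start + 63), 30)
        assert build_arrays([cand], seq) == []

    def test_tandem_repeat_rejected(self, rng):
        unit = random_seq(rng, 60)
        seq = random_seq(rng, 2_000) + unit * 6 + random_seq(rng, 2_000)
        assert detect_arrays(seq) == []


class TestFilterArrays:
    def _array(self, rng, lengths):
        spacers = [random_seq(rng, L) for L in lengths]
        repeat = random_seq(rng, 30)
        return SpacerArray(contig="c", start=0, end=0,
                           repeats=[repeat] * (len(spacers) + 1),
                           spacers=spacers, consensus_repeat=repeat,
                           spacer_positions=[(-1, -1)] * len(spacers))

    def test_50bp_spacer_removed(self, rng):
        arr = self._array(rng, [32, 50, 33])
        out = filter_arrays([arr])
        assert [len(s) for s in out[0].spacers] == [32, 33]

    def test_array_of_long_spacers_dropped(self, rng):
        assert filter_arrays([self._array(rng, [60, 60, 60])]) == []

    def test_compliant_array_unchanged(self, rng):
        arr = self._array(rng, [30, 31, 32])
        out = filter_arrays([arr])
        assert out[0].spacers == arr.spacers

    def test_idempotent(self, rng):
        arrs = [self._array(rng, [14, 30, 49, 50])]
        once = filter_arrays(arrs)
        twice = filter_arrays(once)
        assert [a.spacers for a in once] == [a.spacers for a in twice]


class TestOnSimulatedGenomes:
    def test_planted_arrays_recovered_exactly(self):
        cfg = SimConfig(genome_length=60_000, n_arrays=2, n_initial_spacers=8,
                        seed=21)
        g = simulate_ancestor(cfg)
        detected = {tuple(a.spacers) for a in detect_arrays(g.seq)}
        for planted in g.arrays:
            assert tuple(planted.spacers) in detected

    def test_spacer_table_coordinates_slice_back(self, small_genome):
        arrays = detect_arrays(small_genome.seq, genome_id="g")
        tab = spacer_table(arrays)
        assert len(tab) == sum(len(a.spacers) for a in arrays)
        for _, row in tab.iterrows():
            assert small_genome.seq[row["start"]:row["end"]] == row["sequence"]
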