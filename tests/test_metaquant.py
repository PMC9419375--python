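"""RSR references, read recruitment, classification and abundance relations."""

import numpy as np
import pandas as pd
import pytest

from spacerscan._seq import random_seq, revcomp
from spacerscan.array_detect import SpacerArray
from spacerscan.metaquant import (RSRReference, ReadHit, abundance_regressions,
                                  build_rsr_references, classify_hit,
                                  map_reads, normalize_cpm, quantify)


def _array(repeat, spacers):
    return SpacerArray(contig="c", start=0, end=0,
                       repeats=[repeat] * (len(spacers) + 1), spacers=spacers,
                       consensus_repeat=repeat,
                       spacer_positions=[(-1, -1)] * len(spacers))


class TestReferences:
    def test_one_reference_per_spacer(self, rng):
        R = random_seq(rng, 28)
        s1, s2 = random_seq(rng, 33), random_seq(rng, 35)
        refs = build_rsr_references([_array(R, [s1, s2])])
        assert [r.seq for r in refs] == [R + s1 + R, R + s2 + R]

    def test_duplicate_spacer_dereplicated(self, rng):
        R1, R2 = random_seq(rng, 28), random_seq(rng, 30)
        s = random_seq(rng, 33)
        refs = build_rsr_references([_array(R1, [s]), _array(R2, [s])])
        assert len(refs) == 1
        assert refs[0].repeat == R1  # first carrier supplies the flanks

    def test_layout_intervals(self):
        ref = RSRReference("r", "A" * 28, "C" * 40)
        assert ref.layout == ((0, 28), (28, 68), (68, 96))


class TestMapping:
    def test_exact_reference_copy_maps_fully(self, rng):
        R, s = random_seq(rng, 28), random_seq(rng, 34)
        ref = RSRReference("rsr_00000", R, s)
        hits = map_reads([("r0", ref.seq + random_seq(rng, 150 - len(ref.seq)))],
                         [ref])
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end) == (0, len(ref.seq))
        assert h.mismatches == 0

    def test_spacer_in_phage_context_maps_to_spacer_interval(self, rng):
        R, s = random_seq(rng, 28), random_seq(rng, 34)
        ref = RSRReference("rsr_00000", R, s)
        read = random_seq(rng, 58) + s + random_seq(rng, 58)
        hits = map_reads([("r0", read)], [ref])
        assert len(hits) == 1
        (s0, s1) = ref.layout[1]
        # chance matches may extend the block a base or two into the repeats
        assert abs(hits[0].start - s0) <= 2 and abs(hits[0].end - s1) <= 2

    def test_read_without_shared_kmer_unmapped(self, rng):
        ref = RSRReference("rsr_00000", random_seq(rng, 28), random_seq(rng, 34))
        assert map_reads([("r0", random_seq(rng, 150))], [ref]) == []

    def test_reverse_strand_hit_reported_in_forward_coords(self, rng):
        R, s = random_seq(rng, 28), random_seq(rng, 34)
        ref = RSRReference("rsr_00000", R, s)
        read = revcomp(ref.seq) + random_seq(rng, 150 - len(ref.seq))
        hits = map_reads([("r0", read)], [ref])
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (0, len(ref.seq))


class TestClassification:
    @pytest.fixture
    def ref(self):
        return RSRReference("r", "A" * 28, "C" * 40)  # layout 0-28/28-68/68-96

    def _hit(self, start, end):
        return ReadHit("read", "r", start, end, 0, "+")

    def test_spacer_only_interval_is_protospacer(self, ref):
        assert classify_hit(self._hit(28, 68), ref) == "protospacer"

    def test_repeat_and_spacer_interval_is_array(self, ref):
        assert classify_hit(self._hit(10, 60), ref) == "array"

    def test_small_spacer_fraction_is_ambiguous(self, ref):
        assert classify_hit(self._hit(30, 40), ref) == "ambiguous"

    def test_deep_repeat_incursion_is_not_protospacer(self, ref):
        # 6 bp into the left repeat: too deep for a protospacer call,
        # enough repeat overlap for an array call
        assert classify_hit(self._hit(22, 68), ref) == "array"
        # 4 bp incursion: disqualified from protospacer, short of the 5 bp
        # array requirement -> ambiguous
        assert classify_hit(self._hit(24, 68), ref) == "ambiguous"


class TestQuantify:
    def test_cpm_arithmetic(self):
        counts = pd.DataFrame({"spacer_count": [12], "protospacer_count": [0],
                               "ambiguous_count": [0]}, index=["r"])
        out = normalize_cpm(counts, 3_000_000)
        assert out.loc["r", "spacer_cpm"] == 4.0
        assert out.loc["r", "protospacer_cpm"] == 0.0

    def test_read_conservation(self, rng):
        R = random_seq(rng, 30)
        spacers = [random_seq(rng, 34) for _ in range(3)]
        refs = build_rsr_references([_array(R, spacers)])
        genome = random_seq(rng, 2_000) + refs[0].seq[:30] \
            + "".join(s + R for s in spacers) + random_seq(rng, 2_000)
        from spacerscan.simdata import simulate_metagenome
        reads, _ = simulate_metagenome([("g", genome)], [1.0], 3_000, seed=5)
        table, summary = quantify(reads, refs)
        assert sum(summary["totals"].values()) == summary["n_reads"] == 3_000

    def test_regression_on_exact_powerlaw(self):
        spacer_cpm = np.array([1.0, 10.0, 100.0, 1000.0])
        table = pd.DataFrame({
            "spacer_count": [1] * 4, "protospacer_count": [1] * 4,
            "ambiguous_count": [0] * 4,
            "spacer_cpm": spacer_cpm,
            "protospacer_cpm": spacer_cpm ** 0.5,
        })
        out = abundance_regressions(table)
        assert out["proto_vs_spacer"]["slope"] == pytest.approx(0.5)
        assert out["proto_vs_spacer"]["r2"] == pytest.approx(1.0)
        assert out["ratio_vs_spacer"]["slope"] == pytest.approx(-0.5)

    def test_class_tally(self):
        table = pd.DataFrame({
            "spacer_count": [0, 1, 1, 1], "protospacer_count": [1, 0, 1, 1],
            "ambiguous_count": [0] * 4,
            "spacer_cpm": [0.0, 1.0, 1.0, 2.0],
            "protospacer_cpm": [1.0, 0.0, 2.0, 1.0],
        })
        out = abundance_regressions(table)
        assert out["tally"] == {"protospacer_only": 1, "spacer_only": 1, "both": 2}
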