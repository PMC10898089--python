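"""Contig splitting, chunking, and low-complexity / transposon masking."""

import math
from collections import Counter

import numpy as np
import pytest

from contamscreen.hashing import encode_sequence
from contamscreen.preprocess import (
    Contig,
    chunk_contig,
    detect_transposon_hmers,
    hexamer_entropy,
    mask_low_complexity,
    scaffold_n80,
    split_on_n_runs,
)
from contamscreen.simulate import random_genome


class TestSplitOnNRuns:
    def test_ten_n_run_splits(self):
        contigs = split_on_n_runs("s", "ACGT" + "N" * 10 + "ACGT")
        assert [(c.offset, c.sequence) for c in contigs] == [(0, "ACGT"), (14, "ACGT")]

    def test_nine_n_run_is_retained(self):
        contigs = split_on_n_runs("s", "ACGT" + "N" * 9 + "ACGT")
        assert len(contigs) == 1
        assert contigs[0].sequence == "ACGT" + "N" * 9 + "ACGT"

    def test_all_n_scaffold_yields_nothing(self):
        assert split_on_n_runs("s", "N" * 100) == []

    def test_reassembly_reproduces_scaffold(self):
        rng = np.random.default_rng(0)
        parts = []
        for i in range(6):
            parts.append(random_genome(rng.integers(5, 200), 0.5, rng))
            parts.append("N" * int(rng.integers(1, 30)))
        scaffold = "".join(parts)[:-1]
        contigs = split_on_n_runs("s", scaffold)
        rebuilt = list("N" * len(scaffold))
        for c in contigs:
            rebuilt[c.offset : c.offset + c.length] = c.sequence
        assert "".join(rebuilt) == scaffold


class TestChunking:
    @pytest.mark.parametrize(
        "length, starts",
        [
            (100_000, [0]),
            (250_100, [0, 99_900, 199_800]),
            (100_001, [0, 99_900]),
            (500, [0]),
        ],
    )
    def test_chunk_starts(self, length, starts):
        contig = Contig("s", 0, 0, "A" * length)
        chunks = chunk_contig(contig)
        assert [c.start for c in chunks] == starts
        assert chunks[-1].end == length

    def test_second_chunk_length_101(self):
        chunks = chunk_contig(Contig("s", 0, 0, "A" * 100_001))
        assert chunks[1].length == 101

    def test_chunks_cover_contig_with_exact_overlap(self):
        contig = Contig("s", 0, 0, "A" * 345_678)
        chunks = chunk_contig(contig)
        for a, b in zip(chunks, chunks[1:]):
            assert a.end - b.start == 100
        covered = set()
        for c in chunks:
            covered.update(range(c.start, c.end))
        assert covered == set(range(contig.length))


class TestLowComplexity:
    def test_homopolymer_fully_masked(self):
        assert mask_low_complexity("A" * 200) == [(0, 200)]

    def test_distinct_hexamer_window_not_masked(self):
        # a window whose 45 hexamers are all distinct: entropy log2(45) ~ 5.49
        rng = np.random.default_rng(5)
        for _ in range(50):
            w = random_genome(50, 0.5, rng)
            codes, _f = encode_sequence(w)
            if len({w[i : i + 6] for i in range(45)}) == 45:
                assert math.isclose(hexamer_entropy(codes), math.log2(45), rel_tol=1e-12)
                assert mask_low_complexity(w) == []
                break
        else:
            pytest.fail("no all-distinct window found")

    def test_dinucleotide_repeat_masked(self):
        # (AC)n: two hexamer types with counts 23/22 -> entropy ~ 1.00 bit
        w = "AC" * 25
        codes, _f = encode_sequence(w)
        h = hexamer_entropy(codes)
        assert abs(h - 1.0) < 0.01
        assert mask_low_complexity(w) == [(0, 50)]

    def test_short_sequence_single_window(self):
        assert mask_low_complexity("A" * 30) == [(0, 30)]
        assert mask_low_complexity("ACG") == []  # shorter than one hexamer

    def test_entropy_oracle_on_random_windows(self):
        """Sliding-window decisions match a brute-force hexamer histogram."""
        rng = np.random.default_rng(11)
        seq = "".join(
            ("AT" * 40) if rng.random() < 0.3 else random_genome(80, 0.5, rng)
            for _ in range(20)
        )
        masked = mask_low_complexity(seq)
        bitmap = np.zeros(len(seq), dtype=bool)
        for s, e in masked:
            bitmap[s:e] = True
        expected = np.zeros(len(seq), dtype=bool)
        for i in range(len(seq) - 49):
            counts = Counter(seq[i + j : i + j + 6] for j in range(45))
            total = sum(counts.values())
            h = -sum((c / total) * math.log2(c / total) for c in counts.values())
            if h < 4.5:
                expected[i : i + 50] = True
        assert np.array_equal(bitmap, expected)

    def test_masking_stable_under_hardmasking(self):
        """Hardmasking flagged spans never un-flags them on a re-run.

        Replacing a masked span with a homopolymer can only lower window
        entropy, so the re-run mask must contain the original intervals and
        may extend them by at most one window at each boundary.
        """
        rng = np.random.default_rng(13)
        seq = random_genome(300, 0.5, rng) + "AG" * 100 + random_genome(300, 0.5, rng)
        first = mask_low_complexity(seq)
        assert first  # the dinucleotide repeat is flagged
        hard = list(seq)
        for s, e in first:
            hard[s:e] = "A" * (e - s)
        second = mask_low_complexity("".join(hard))
        for s, e in first:
            assert any(s2 <= s and e <= e2 for s2, e2 in second)
        for s2, e2 in second:
            assert any(s - 50 <= s2 and e2 <= e + 50 for s, e in first)


class TestTransposonDetection:
    def test_repeated_element_flagged_flanks_clean(self):
        rng = np.random.default_rng(3)
        element = random_genome(5_000, 0.5, rng)
        parts = [random_genome(3_000, 0.5, rng)]
        for _ in range(15):
            parts.append(element)
            parts.append(random_genome(1_000, 0.5, rng))
        genome = "".join(parts)
        codes, _f = encode_sequence(genome, "g")
        flagged, tracks = detect_transposon_hmers([("g", codes)], [len(genome)])
        assert len(flagged) > 0
        masked = sum(e - s for s, e in tracks["g"])
        # repeats cover most of the genome here; flanks stay unmasked
        assert 0 < masked < len(genome)

    def test_short_sequences_excluded_from_statistics(self):
        """phiX-like genomes of many short copies produce no repeat track."""
        rng = np.random.default_rng(4)
        phix = random_genome(5_000, 0.5, rng)
        contigs = []
        for i in range(30):
            codes, _f = encode_sequence(phix, f"c{i}")
            contigs.append((f"c{i}", codes))
        # scaffold N80 is 5 kbp, but the scope floor is min(100 kbp, N80)
        # with a long decoy scaffold: short copies fall below the scope
        long_seq = random_genome(120_000, 0.5, rng)
        codes, _f = encode_sequence(long_seq, "long")
        contigs.append(("long", codes))
        flagged, tracks = detect_transposon_hmers(
            contigs, [5_000] * 30 + [120_000 * 10]
        )
        assert len(flagged) == 0
        assert all(not t for t in tracks.values())


def test_scaffold_n80_convention():
    assert scaffold_n80([100, 100, 100, 100, 100]) == 100
    assert scaffold_n80([50, 30, 10, 5, 5]) == 30
    assert scaffold_n80([]) == 0
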