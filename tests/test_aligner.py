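"""Alignment: scoring, seed noise filtering, taxa selection, extension."""

import math

import edlib
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from contamscreen.aligner import (
    Pass1TaxonStats,
    align_contig,
    run_pass1,
    score_alignment,
    select_taxa,
)
from contamscreen.config import ScreenConfig
from contamscreen.hashing import encode_sequence
from contamscreen.hmer_index import build_database
from contamscreen.simulate import derive_strain, random_genome
from contamscreen.taxonomy import default_table


def _db(*records, stride=10):
    return build_database(list(records), default_table(), stride=stride)


def _align_pair(query: str, subject: str, taxid=562, cfg=None):
    """Align a query against a single-subject database, returning hits."""
    cfg = cfg or ScreenConfig()
    db = _db(("subj", taxid, subject))
    codes, filled = encode_sequence(query, "q")
    hits, stats = align_contig("q", codes, filled, [(0, len(codes))], db, cfg)
    return hits, stats


class TestScore:
    @pytest.mark.parametrize(
        "segments, expected",
        [([100], 100.0), ([30, 40], 50.0), ([], 0.0), ([1], 1.0)],
    )
    def test_examples(self, segments, expected):
        assert score_alignment(segments) == pytest.approx(expected)

    def test_clustered_mismatches_score_below_unbroken_run(self):
        assert score_alignment([60, 60]) == pytest.approx(math.sqrt(7200))
        assert score_alignment([60, 60]) < score_alignment([120])

    @given(st.lists(st.integers(1, 500), max_size=20), st.integers(1, 500))
    def test_appending_never_decreases_splitting_always_decreases(self, segs, extra):
        assert score_alignment(segs + [extra]) >= score_alignment(segs)
        if extra >= 2:
            k = extra // 2
            assert score_alignment(segs + [k, extra - k]) < score_alignment(segs + [extra])


class TestPass1:
    def test_lone_seed_removed_by_noise_filter(self):
        rng = np.random.default_rng(0)
        subject = random_genome(5_000, 0.5, rng)
        # a single 56-bp island of identity inside an unrelated query
        query = random_genome(2_000, 0.5, rng) + subject[1000:1056] + random_genome(
            2_000, 0.5, rng
        )
        db = _db(("s", 562, subject))
        codes, _f = encode_sequence(query, "q")
        runs, stats = run_pass1(codes, 0, db, ScreenConfig())
        assert runs == [] and stats == {}

    def test_neighbouring_seeds_survive(self):
        rng = np.random.default_rng(1)
        subject = random_genome(5_000, 0.5, rng)
        # two 56-bp islands 500 bp apart on the same diagonal
        q = list(random_genome(2_000, 0.5, rng))
        q[300:356] = subject[1300:1356]
        q[800:856] = subject[1800:1856]
        db = _db(("s", 562, subject))
        codes, _f = encode_sequence("".join(q), "q")
        runs, stats = run_pass1(codes, 0, db, ScreenConfig())
        assert stats and 562 in stats
        assert stats[562].sum_len >= 112

    def test_identical_query_gives_full_coverage_run(self):
        rng = np.random.default_rng(2)
        subject = random_genome(8_000, 0.5, rng)
        db = _db(("s", 562, subject))
        codes, _f = encode_sequence(subject, "q")
        runs, stats = run_pass1(codes, 0, db, ScreenConfig())
        assert stats[562].max_len >= len(subject) * 0.99


class TestSelectTaxa:
    def test_singleton(self):
        assert select_taxa({7: Pass1TaxonStats(1, 10, 10, 100)}) == {7}

    def test_taxon_fourth_on_three_metrics_second_on_max_len_retained(self):
        stats = {}
        # taxa 1..4 dominate count/sum/sum_sq; taxon 5 sneaks in via max_len
        for t, (n, mx) in enumerate(
            [(40, 50), (30, 45), (20, 40), (10, 35), (2, 48)], start=1
        ):
            s = Pass1TaxonStats()
            for _ in range(n):
                s.add(mx)
            stats[t] = s
        assert 5 in select_taxa(stats)

    def test_cardinality_bound_is_twelve(self):
        stats = {t: Pass1TaxonStats(t, t * 2, t * 3, t * 4) for t in range(1, 30)}
        assert len(select_taxa(stats)) <= 12


class TestPass2:
    def test_snp_yields_two_identity_segments(self):
        rng = np.random.default_rng(3)
        subject = random_genome(2_000, 0.5, rng)
        mid = 1_000
        # transversion so the base genuinely differs in 2-bit space
        swapped = {"A": "C", "C": "A", "G": "T", "T": "G"}[subject[mid]]
        query = subject[:mid] + swapped + subject[mid + 1 :]
        hits, _ = _align_pair(query, subject)
        assert len(hits) == 1
        segs = sorted(hits[0].identity_segments, reverse=True)
        assert len(segs) == 2
        assert sorted(segs) == sorted([mid - hits[0].q_start, hits[0].q_end - mid - 1])

    def test_insertion_yields_gapped_hit_spanning_indel(self):
        rng = np.random.default_rng(4)
        subject = random_genome(2_000, 0.5, rng)
        query = subject[:1000] + "ACG" + subject[1000:]
        hits, _ = _align_pair(query, subject)
        assert len(hits) == 1
        h = hits[0]
        assert h.q_end - h.q_start >= len(query) - 10
        assert len(h.identity_segments) >= 2

    def test_no_selected_taxa_gives_empty_hits(self):
        from contamscreen.aligner import run_pass2

        rng = np.random.default_rng(5)
        subject = random_genome(2_000, 0.5, rng)
        db = _db(("s", 562, subject))
        codes, filled = encode_sequence(subject, "q")
        assert run_pass2("q", codes, filled, [(0, 2000)], db, set(), [], ScreenConfig()) == []

    def test_self_alignment_attains_99_percent_coverage(self):
        rng = np.random.default_rng(6)
        for taxid, length in [(562, 12_000), (9606, 7_000)]:
            subject = random_genome(length, 0.45, rng)
            hits, _ = _align_pair(subject, subject, taxid=taxid)
            covered = sum(h.q_end - h.q_start for h in hits)
            assert covered >= 0.99 * length


class TestStrandSymmetry:
    def test_reverse_complement_query_mirrors_hits(self):
        from contamscreen.hashing import reverse_complement

        rng = np.random.default_rng(7)
        subject = random_genome(6_000, 0.5, rng)
        query = derive_strain(subject, 0.02, 0.0, np.random.default_rng(8))
        fwd, _ = _align_pair(query, subject)
        rev, _ = _align_pair(reverse_complement(query), subject)
        n = len(query)
        fwd_ivs = sorted((h.q_start, h.q_end) for h in fwd)
        rev_ivs = sorted((n - h.q_end, n - h.q_start) for h in rev)
        assert fwd_ivs == rev_ivs
        assert sorted(h.score for h in fwd) == pytest.approx(
            sorted(h.score for h in rev)
        )


class TestDpOracle:
    def test_identity_segments_agree_with_edit_distance_alignment(self):
        """On short diverged pairs, refined scores track a DP alignment.

        edlib's optimal path defines exact-match run lengths; the heuristic
        extension must agree on at least 95% of random fixtures (scores
        within 10%), without claiming path-level equality.
        """
        rng = np.random.default_rng(9)
        agree = 0
        trials = 20
        for t in range(trials):
            subject = random_genome(1_500, 0.5, rng)
            query = derive_strain(subject, 0.02, 0.001, rng)
            hits, _ = _align_pair(query, subject)
            got = math.sqrt(
                sum(l * l for h in hits for l in h.identity_segments)
            )
            res = edlib.align(query, subject, task="path", mode="NW")
            runs = [
                int(n)
                for n, op in _cigar_ops(res["cigar"])
                if op == "="
            ]
            want = math.sqrt(sum(l * l for l in runs))
            if want and abs(got - want) / want <= 0.10:
                agree += 1
        assert agree >= 0.95 * trials


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""
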