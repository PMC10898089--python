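"""Contamination calling thresholds, exercised on synthetic report fixtures."""

import pandas as pd
import pytest

from contamscreen.classifier import (
    ContaminationCall,
    ScreenContext,
    aggregate_divisions,
    assign_action,
    call_sequence,
    coverage_cutoff,
    flag_contaminant_divisions,
    infer_primary_set,
)
from contamscreen.config import ScreenConfig
from contamscreen.taxonomy import DivisionSummary, Lineage, SequenceReport, SpeciesSummary

CFG = ScreenConfig()
HOST = Lineage("Hostus maximus", "anml:primates", "Metazoa")


def _report(seq_id, length, divisions, species=None, lc=None, tx=None, cons=None):
    """Build a SequenceReport from (division, kingdom, intervals, score) rows."""
    rep = SequenceReport(seq_id=seq_id, length=length)
    rep.low_complexity = lc or []
    rep.transposon = tx or []
    rep.conserved = cons or []
    from contamscreen import intervals as iv

    for i, (div, kingdom, ivs, score) in enumerate(divisions):
        cov = sum(e - s for s, e in ivs)
        rep.divisions[div] = DivisionSummary(
            division=div, kingdom=kingdom, intervals=ivs, coverage=cov, score=score,
            low_complexity_bp=iv.intersect_length(ivs, rep.low_complexity),
            transposon_bp=iv.intersect_length(ivs, rep.transposon),
            conserved_bp=iv.intersect_length(ivs, rep.conserved),
        )
        taxid = 100 + i
        rep.species[taxid] = SpeciesSummary(
            taxid=taxid, species=f"sp{i}", division=div, kingdom=kingdom,
            intervals=ivs, coverage=cov, score=score, segment_sq_sum=score * score,
        )
        rep.retained.append(taxid)
    rep.top_hit_coverage = min(
        length, sum(e - s for _d, _k, ivs, _s in divisions for s, e in ivs)
    )
    return rep


def _context(**kw):
    defaults = dict(
        declared_taxid=1,
        declared=HOST,
        genome_length=1_000_000,
        aggregate_coverage=1.0,
        primary_divisions={HOST.division},
    )
    defaults.update(kw)
    return ScreenContext(**defaults)


class TestCoverageCutoff:
    @pytest.mark.parametrize(
        "fraction, expected",
        [(1.0, 0.2), (0.0, 0.6), (2 / 3, 0.2), (0.5, 0.3)],
    )
    def test_examples(self, fraction, expected):
        assert coverage_cutoff(fraction) == pytest.approx(expected)


class TestAggregateFilters:
    def _reports(self, score, cov_frac):
        length = 10_000
        ivs = [(0, int(cov_frac * length))]
        return [
            _report("q", length, [("prok:x", "Bacteria", ivs, score)]),
        ]

    @pytest.mark.parametrize(
        "score, included", [(149.0, False), (150.0, True), (151.0, True)]
    )
    def test_score_filter_boundary(self, score, included):
        aggs = aggregate_divisions(self._reports(score, 0.9), HOST.division, CFG)
        assert ("prok:x" in aggs) is included

    @pytest.mark.parametrize(
        "cov, included", [(0.80, False), (0.805, True), (1.0, True)]
    )
    def test_coverage_filter_strictly_above_80(self, cov, included):
        aggs = aggregate_divisions(self._reports(500.0, cov), HOST.division, CFG)
        assert ("prok:x" in aggs) is included

    def test_no_qualifying_alignments_flags_nothing(self):
        aggs = aggregate_divisions(self._reports(100.0, 0.5), HOST.division, CFG)
        assert aggs == {}
        assert flag_contaminant_divisions(aggs, CFG) == set()


class TestFlagCriteria:
    def _agg_reports(self, n_seqs=2, seq_len=10_000, lc=None, tx=None, source=False):
        reports = []
        for i in range(n_seqs):
            divisions = [("prok:x", "Bacteria", [(0, seq_len)], 5_000.0)]
            if source:
                divisions.append((HOST.division, HOST.kingdom, [(0, seq_len)], 5_000.0))
            reports.append(
                _report(f"q{i}", seq_len, divisions, lc=lc, tx=tx)
            )
        return reports

    def test_clean_contaminant_division_flagged(self):
        aggs = aggregate_divisions(self._agg_reports(), HOST.division, CFG)
        assert flag_contaminant_divisions(aggs, CFG) == {"prok:x"}
        agg = aggs["prok:x"]
        assert agg.nonrepetitive_bp == 20_000

    def test_nonrepetitive_below_10kbp_not_flagged(self):
        aggs = aggregate_divisions(
            self._agg_reports(n_seqs=1, seq_len=9_000), HOST.division, CFG
        )
        assert flag_contaminant_divisions(aggs, CFG) == set()

    def test_exactly_10kbp_not_flagged_strictly_more_is(self):
        aggs = aggregate_divisions(
            self._agg_reports(n_seqs=1, seq_len=10_000), HOST.division, CFG
        )
        assert flag_contaminant_divisions(aggs, CFG) == set()
        aggs = aggregate_divisions(
            self._agg_reports(n_seqs=1, seq_len=10_001), HOST.division, CFG
        )
        assert flag_contaminant_divisions(aggs, CFG) == {"prok:x"}

    def test_low_complexity_above_75_percent_not_flagged(self):
        aggs = aggregate_divisions(
            self._agg_reports(lc=[(0, 8_000)]), HOST.division, CFG
        )
        assert flag_contaminant_divisions(aggs, CFG) == set()

    def test_source_overlap_above_75_percent_not_flagged(self):
        aggs = aggregate_divisions(
            self._agg_reports(source=True), HOST.division, CFG
        )
        assert aggs["prok:x"].source_overlap_frac == pytest.approx(1.0)
        assert flag_contaminant_divisions(aggs, CFG) == set()


class TestCallSequence:
    def _single(self, score, flagged=True, length=10_000, cov_frac=1.0, kingdom="Bacteria"):
        ivs = [(0, int(cov_frac * length))]
        rep = _report("q", length, [("prok:x", kingdom, ivs, score)])
        ctx = _context()
        flags = {"prok:x"} if flagged else set()
        return call_sequence(rep, flags, ctx, CFG)

    @pytest.mark.parametrize("score, called", [(50.0, False), (50.5, True), (51.0, True)])
    def test_flagged_score_strictly_above_50(self, score, called):
        # coverage 50% keeps the inter-kingdom >=80% alternative rule out of
        # play so the score boundary itself decides (cutoff here is 20%)
        calls = self._single(score, flagged=True, cov_frac=0.5)
        got = any(c.category == "contaminant" and not c.low_confidence for c in calls)
        assert got is called

    @pytest.mark.parametrize("score, called", [(100.0, False), (101.0, True)])
    def test_unflagged_score_strictly_above_100(self, score, called):
        calls = self._single(score, flagged=False)
        assert any(c.category == "contaminant" for c in calls) is called

    def test_unflagged_repeat_content_below_50_percent(self):
        length = 10_000
        rep = _report(
            "q", length,
            [("prok:x", "Bacteria", [(0, length)], 500.0)],
            lc=[(0, 6_000)],
        )
        calls = call_sequence(rep, set(), _context(), CFG)
        assert not any(c.category == "contaminant" for c in calls)
        rep = _report(
            "q", length,
            [("prok:x", "Bacteria", [(0, length)], 500.0)],
            lc=[(0, 4_000)],
        )
        calls = call_sequence(rep, set(), _context(), CFG)
        assert any(c.category == "contaminant" for c in calls)

    def test_zero_alignments_inconclusive(self):
        rep = SequenceReport(seq_id="q", length=5_000)
        calls = call_sequence(rep, set(), _context(), CFG)
        assert [c.category for c in calls] == ["inconclusive"]

    def test_interkingdom_low_score_high_coverage_called(self):
        calls = self._single(40.0, flagged=True, cov_frac=0.85)
        assert any(c.category == "contaminant" and not c.low_confidence for c in calls)

    def test_coverage_below_cutoff_blocks_call(self):
        # aggregate coverage 0 -> cutoff 0.6; contaminant covering 30% fails
        ivs = [(0, 3_000)]
        rep = _report("q", 10_000, [("prok:x", "Bacteria", ivs, 5_000.0)])
        ctx = _context(aggregate_coverage=0.0)
        calls = call_sequence(rep, {"prok:x"}, ctx, CFG)
        assert all(c.low_confidence for c in calls if c.category == "contaminant")


class TestActions:
    def _call(self, whole=True, ranges=None, kingdom="Bacteria", division="prok:x",
              length=100_000, low_confidence=False):
        return ContaminationCall(
            seq_id="q", seq_length=length, category="contaminant",
            division=division, kingdom=kingdom,
            ranges=ranges or [(0, length)], whole_sequence=whole,
            low_confidence=low_confidence,
        )

    def test_whole_sequence_contaminant_excluded(self):
        assert assign_action(self._call(), _context(), CFG) == "EXCLUDE"

    def test_interkingdom_terminal_span_trims_internal_fixes(self):
        terminal = self._call(whole=False, ranges=[(99_000, 100_000)])
        internal = self._call(whole=False, ranges=[(40_000, 60_000)])
        assert assign_action(terminal, _context(), CFG) == "TRIM"
        assert assign_action(internal, _context(), CFG) == "FIX"

    def test_intra_kingdom_chimera_span_boundary(self):
        ctx = _context()
        small = self._call(
            whole=False, ranges=[(50_000, 59_000)], kingdom="Metazoa", division="anml:x"
        )
        big = self._call(
            whole=False, ranges=[(50_000, 61_000)], kingdom="Metazoa", division="anml:x"
        )
        assert assign_action(small, ctx, CFG) is None
        assert assign_action(big, ctx, CFG) == "REVIEW"

    def test_known_lgt_source_chimera_is_info(self):
        call = self._call(
            whole=False, ranges=[(40_000, 45_000)],
            division="prok:a-proteobacteria", kingdom="Bacteria",
        )
        assert assign_action(call, _context(), CFG) == "INFO"

    def test_virus_rules(self):
        euk = _context()
        prok = _context(declared=Lineage("B", "prok:y", "Bacteria"),
                        primary_divisions={"prok:y"})
        whole_virus = self._call(kingdom="Viruses", division="virs:prokaryotic viruses")
        chim_virus = self._call(
            whole=False, ranges=[(0, 1_000)],
            kingdom="Viruses", division="virs:eukaryotic viruses",
        )
        assert assign_action(whole_virus, euk, CFG) == "EXCLUDE"
        assert assign_action(chim_virus, euk, CFG) is None
        assert assign_action(whole_virus, prok, CFG) is None


class TestPrimaryInference:
    def _db_stats(self, divisions):
        return pd.DataFrame(
            [(d, "Metazoa", 5, 10_000_000) for d in divisions],
            columns=["division", "kingdom", "n_sequences", "total_bp"],
        )

    def test_high_overlap_same_kingdom_division_joins_primary(self):
        reports = [
            _report("q", 100_000, [
                (HOST.division, HOST.kingdom, [(0, 90_000)], 9_000.0),
                ("anml:rodents", "Metazoa", [(0, 85_000)], 5_000.0),
            ])
        ]
        primary, warnings = infer_primary_set(
            reports, HOST, 0.9, self._db_stats([HOST.division]), CFG
        )
        assert primary == {HOST.division, "anml:rodents"}
        assert warnings == []

    def test_low_overlap_division_stays_contaminant_candidate(self):
        reports = [
            _report("q", 100_000, [
                (HOST.division, HOST.kingdom, [(0, 90_000)], 9_000.0),
                ("anml:rodents", "Metazoa", [(90_000, 99_000)], 5_000.0),
            ])
        ]
        primary, _ = infer_primary_set(
            reports, HOST, 0.9, self._db_stats([HOST.division]), CFG
        )
        assert "anml:rodents" not in primary

    def test_wrong_taxid_warning_when_declared_absent_but_represented(self):
        reports = [
            _report("q", 100_000, [("prok:x", "Bacteria", [(0, 95_000)], 9_000.0)])
        ]
        primary, warnings = infer_primary_set(
            reports, HOST, 0.95, self._db_stats([HOST.division]), CFG
        )
        assert primary == {HOST.division}
        assert warnings and "declared" in warnings[0]

    def test_poorly_represented_declared_division_trusts_inference(self):
        reports = [
            _report("q", 100_000, [("prok:x", "Bacteria", [(0, 95_000)], 9_000.0)])
        ]
        primary, warnings = infer_primary_set(
            reports, HOST, 0.2, self._db_stats([]), CFG
        )
        assert HOST.division in primary and "prok:x" in primary
        assert warnings == []
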