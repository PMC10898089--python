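"""Contamination calling: aggregate statistics, per-sequence calls, actions.

Calling proceeds genome-wide first, per sequence second:

1. aggregate statistics per taxonomic division, from alignments passing a
   score filter (>= 150) and a coverage filter (> 80% of their sequence);
2. divisions flagged as high-confidence contamination sources when all four
   criteria hold: (a) < 75% of aligned regions are low-complexity/conserved,
   (b) < 75% are transposon-like repeats, (c) > 10 kbp of aligned regions
   are non-repetitive, (d) < 75% overlap alignments to the declared source
   division;
3. an inferred primary-division set: same-kingdom divisions whose
   alignments highly overlap the top-coverage division are treated as the
   source organism (with a dynamic concordance threshold that relaxes for
   genomes poorly covered by the database); a declared division that is
   well represented in the database yet absent from the inferred set turns
   the inferred divisions into contaminants and emits a wrong-taxid
   warning;
4. per-sequence calls: flagged divisions need score > 50 (or inter-kingdom
   coverage >= 80%), unflagged divisions need score > 100 with
   repeat/conserved content < 50%; every call must clear the minimum
   coverage cutoff ``max(0.2, 0.6 x (1 - aggregate coverage fraction))``;
   sequences with zero alignments are inconclusive;
5. actions: whole-sequence contaminants EXCLUDE; inter-kingdom chimeric
   spans TRIM (terminal) or FIX (internal); known-LGT-source chimeras INFO;
   intra-kingdom chimeras >= 10 kbp REVIEW (smaller ones are ignored);
   prokaryote-in-prokaryote contamination totalling <= 1% of the genome
   REVIEW_RARE; virus calls follow conservative host-dependent rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import intervals as iv
from .config import ScreenConfig
from .intervals import Interval
from .taxonomy import Lineage, SequenceReport, superkingdom

__all__ = [
    "Action",
    "ContaminationCall",
    "DivisionAggregate",
    "ScreenContext",
    "aggregate_divisions",
    "assign_action",
    "call_sequence",
    "coverage_cutoff",
    "flag_contaminant_divisions",
    "infer_primary_set",
    "screen_calls",
]

CORRECTIVE_ACTIONS = ("EXCLUDE", "TRIM", "FIX")
REVIEW_ACTIONS = ("INFO", "REVIEW", "REVIEW_RARE")
Action = str


@dataclass
class DivisionAggregate:
    """Genome-wide statistics for one division, from filtered alignments."""

    division: str
    kingdom: str
    total_bp: int = 0
    low_complexity_conserved_bp: int = 0
    transposon_bp: int = 0
    source_overlap_bp: int = 0
    flagged: bool = False

    @property
    def nonrepetitive_bp(self) -> int:
        return max(0, self.total_bp - self.low_complexity_conserved_bp - self.transposon_bp)

    def _frac(self, bp: int) -> float:
        return bp / self.total_bp if self.total_bp else 0.0

    @property
    def low_complexity_conserved_frac(self) -> float:
        return self._frac(self.low_complexity_conserved_bp)

    @property
    def transposon_frac(self) -> float:
        return self._frac(self.transposon_bp)

    @property
    def source_overlap_frac(self) -> float:
        return self._frac(self.source_overlap_bp)


@dataclass
class ScreenContext:
    """Genome-level inputs to per-sequence calling."""

    declared_taxid: int
    declared: Lineage
    genome_length: int
    aggregate_coverage: float  # top-4-hit aligned length / genome length
    primary_divisions: set[str]
    flagged_divisions: set[str] = field(default_factory=set)
    aggregates: dict[str, DivisionAggregate] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def min_coverage(self) -> float:
        return coverage_cutoff(self.aggregate_coverage)


@dataclass
class ContaminationCall:
    seq_id: str
    seq_length: int
    category: str  # primary | contaminant | inconclusive
    division: str = ""
    kingdom: str = ""
    top_species: str = ""
    ranges: list[Interval] = field(default_factory=list)  # 0-based half-open
    whole_sequence: bool = False
    coverage_percent: float = 0.0
    score: float = 0.0
    action: Action | None = None
    low_confidence: bool = False


def coverage_cutoff(
    aggregate_coverage_fraction: float,
    floor: float = 0.2,
    slope: float = 0.6,
) -> float:
    """Minimum alignment coverage for calling contaminants.

    ``max(0.2, 0.6 x (1 - genome aggregate coverage fraction))``: genomes
    with few close database neighbours require higher per-call coverage.
    """
    return max(floor, slope * (1.0 - aggregate_coverage_fraction))


def aggregate_divisions(
    reports: list[SequenceReport],
    declared_division: str,
    cfg: ScreenConfig | None = None,
) -> dict[str, DivisionAggregate]:
    """Per-division statistics from score- and coverage-filtered alignments.

    A per-sequence division alignment contributes only when its score is at
    least 150 and it covers more than 80% of its sequence.
    """
    cfg = cfg or ScreenConfig()
    aggs: dict[str, DivisionAggregate] = {}
    for rep in reports:
        declared_track = (
            rep.divisions[declared_division].intervals
            if declared_division in rep.divisions
            else []
        )
        for division, ds in rep.divisions.items():
            if division == declared_division:
                continue
            if ds.score < cfg.aggregate_min_score:
                continue
            if rep.length == 0 or ds.coverage / rep.length <= cfg.aggregate_min_coverage:
                continue
            agg = aggs.setdefault(division, DivisionAggregate(division, ds.kingdom))
            agg.total_bp += ds.coverage
            agg.low_complexity_conserved_bp += min(
                ds.coverage, ds.low_complexity_bp + ds.conserved_bp
            )
            agg.transposon_bp += ds.transposon_bp
            agg.source_overlap_bp += iv.intersect_length(ds.intervals, declared_track)
    return aggs


def flag_contaminant_divisions(
    aggregates: dict[str, DivisionAggregate],
    cfg: ScreenConfig | None = None,
) -> set[str]:
    """Divisions meeting all four high-confidence contamination criteria."""
    cfg = cfg or ScreenConfig()
    flagged = set()
    for division, agg in aggregates.items():
        crit_a = agg.low_complexity_conserved_frac < cfg.repeat_fraction_criterion
        crit_b = agg.transposon_frac < cfg.repeat_fraction_criterion
        crit_c = agg.nonrepetitive_bp > cfg.min_nonrepetitive_bp
        crit_d = agg.source_overlap_frac < cfg.repeat_fraction_criterion
        agg.flagged = crit_a and crit_b and crit_c and crit_d
        if agg.flagged:
            flagged.add(division)
    return flagged


def infer_primary_set(
    reports: list[SequenceReport],
    declared: Lineage,
    aggregate_coverage: float,
    db_division_stats,
    cfg: ScreenConfig | None = None,
) -> tuple[set[str], list[str]]:
    """Divisions treated as belonging to the declared source organism.

    Divisions from the same kingdom as the top-coverage division whose
    alignments overlap the top division's alignments above a dynamic
    concordance threshold join the primary set.  The threshold is
    ``max(floor, ceiling x aggregate coverage)`` so poorly represented
    genomes need less concordance.  If the declared division is well
    represented in the database yet absent from the inferred set, the
    inferred divisions are reported as contaminants instead and a wrong-
    taxid warning is emitted.
    """
    cfg = cfg or ScreenConfig()
    warnings: list[str] = []

    div_tracks: dict[str, dict[str, list[Interval]]] = {}
    div_cov: dict[str, int] = {}
    div_kingdom: dict[str, str] = {}
    for rep in reports:
        for division, ds in rep.divisions.items():
            div_tracks.setdefault(division, {})[rep.seq_id] = ds.intervals
            div_cov[division] = div_cov.get(division, 0) + ds.coverage
            div_kingdom[division] = ds.kingdom

    if not div_cov:
        return {declared.division}, warnings

    top_division = min(div_cov, key=lambda d: (-div_cov[d], d))
    threshold = max(cfg.concordance_floor, cfg.concordance_ceiling * aggregate_coverage)

    inferred = {top_division}
    top_tracks = div_tracks[top_division]
    for division, tracks in div_tracks.items():
        if division == top_division or div_kingdom[division] != div_kingdom[top_division]:
            continue
        overlap = sum(
            iv.intersect_length(track, top_tracks.get(seq_id, []))
            for seq_id, track in tracks.items()
        )
        if div_cov[division] and overlap / div_cov[division] >= threshold:
            inferred.add(division)

    if declared.division in inferred:
        return inferred, warnings

    # declared division absent from the inferred set
    stats = db_division_stats
    row = stats.loc[stats["division"] == declared.division] if len(stats) else stats
    well_represented = (
        len(row) > 0
        and int(row["n_sequences"].iloc[0]) >= cfg.well_represented_min_seqs
        and int(row["total_bp"].iloc[0]) >= cfg.well_represented_min_bp
    )
    if well_represented:
        warnings.append(
            f"declared division {declared.division!r} is well represented in the "
            f"database but the assembly has poor coverage from it; inferred "
            f"division(s) {sorted(inferred)} are reported as contaminants -- "
            f"check the declared taxid {declared.species!r}"
        )
        return {declared.division}, warnings
    # rare genome with poor representation: trust the inferred set
    inferred.add(declared.division)
    return inferred, warnings


def _repeat_conserved_content(rep: SequenceReport, intervals: list[Interval]) -> float:
    denom = iv.total_length(intervals)
    if denom == 0:
        return 0.0
    repeat = iv.merge(rep.low_complexity + rep.transposon + rep.conserved)
    return iv.intersect_length(intervals, repeat) / denom


def call_sequence(
    report: SequenceReport,
    flagged: set[str],
    context: ScreenContext,
    cfg: ScreenConfig | None = None,
) -> list[ContaminationCall]:
    """Classify one sequence as primary / contaminant / inconclusive.

    Produces one call per reported contaminant range; a sequence whose
    contaminant division covers essentially everything (no meaningful
    primary-division anchor) yields a single whole-sequence call.
    """
    cfg = cfg or ScreenConfig()
    L = report.length

    if not report.has_hits:
        return [ContaminationCall(report.seq_id, L, "inconclusive")]

    primary_track: list[Interval] = []
    for division in context.primary_divisions:
        if division in report.divisions:
            primary_track.extend(report.divisions[division].intervals)
    primary_track = iv.merge(primary_track)
    primary_len = iv.total_length(primary_track)

    calls: list[ContaminationCall] = []
    candidates = sorted(
        (ds for d, ds in report.divisions.items() if d not in context.primary_divisions),
        key=lambda ds: (-ds.score, ds.division),
    )
    for ds in candidates:
        inter_kingdom = ds.kingdom != context.declared.kingdom
        if ds.division in flagged:
            eligible = ds.score > cfg.flagged_min_score or (
                inter_kingdom
                and L > 0
                and ds.coverage / L >= cfg.interkingdom_min_coverage
            )
        else:
            content = _repeat_conserved_content(report, ds.intervals)
            eligible = (
                ds.score > cfg.unflagged_min_score
                and content < cfg.unflagged_max_repeat_content
            )

        top_species = ""
        best = max(
            (s for s in report.species.values() if s.division == ds.division),
            key=lambda s: (s.score, -s.taxid),
            default=None,
        )
        if best is not None:
            top_species = best.species

        whole = primary_len < min(cfg.min_primary_anchor_bp, L)
        if whole:
            coverage_frac = ds.coverage / L if L else 0.0
            if eligible and coverage_frac >= context.min_coverage:
                calls.append(
                    ContaminationCall(
                        seq_id=report.seq_id,
                        seq_length=L,
                        category="contaminant",
                        division=ds.division,
                        kingdom=ds.kingdom,
                        top_species=top_species,
                        ranges=[(0, L)],
                        whole_sequence=True,
                        coverage_percent=100.0 * coverage_frac,
                        score=ds.score,
                    )
                )
                break  # one whole-sequence contaminant assignment suffices
            if (
                ds.division in flagged
                and ds.score > cfg.flagged_min_score
                and coverage_frac < context.min_coverage
            ):
                # evidence of this contaminant elsewhere in the genome but
                # low coverage here: surface for manual review
                calls.append(
                    ContaminationCall(
                        seq_id=report.seq_id,
                        seq_length=L,
                        category="contaminant",
                        division=ds.division,
                        kingdom=ds.kingdom,
                        top_species=top_species,
                        ranges=[(0, L)],
                        whole_sequence=True,
                        coverage_percent=100.0 * coverage_frac,
                        score=ds.score,
                        low_confidence=True,
                    )
                )
            continue

        # chimeric: contaminant and primary alignments partition the sequence
        if not eligible:
            continue
        # tiny primary slivers (short shared-repeat remnants) must not carve
        # a contaminant span into unreportable pieces
        solid_primary = [p for p in primary_track if p[1] - p[0] >= 100]
        spans = iv.subtract(
            iv.merge(ds.intervals, gap=cfg.chimera_join_gap), solid_primary
        )
        for span in spans:
            span_len = span[1] - span[0]
            if span_len <= 0:
                continue
            aligned = iv.intersect_length(ds.intervals, [span])
            if span_len and aligned / span_len < context.min_coverage:
                continue
            calls.append(
                ContaminationCall(
                    seq_id=report.seq_id,
                    seq_length=L,
                    category="contaminant",
                    division=ds.division,
                    kingdom=ds.kingdom,
                    top_species=top_species,
                    ranges=[span],
                    whole_sequence=False,
                    coverage_percent=100.0 * aligned / span_len,
                    score=ds.score,
                )
            )

    if not calls:
        category = "primary" if primary_len > 0 else "inconclusive"
        return [ContaminationCall(report.seq_id, L, category)]
    return calls


def _is_virus_division(kingdom: str) -> bool:
    return kingdom == "Viruses"


def _virus_superhost(division: str) -> str:
    if "prokaryotic" in division:
        return "prokaryote"
    if "eukaryotic" in division:
        return "eukaryote"
    return "other"


def assign_action(
    call: ContaminationCall,
    context: ScreenContext,
    cfg: ScreenConfig | None = None,
) -> Action | None:
    """Map a contaminant call to one of the six actions, or drop it.

    Returns ``None`` when the call should not be reported (small
    intra-kingdom chimeras, ignored viral elements).  Prokaryote-in-
    prokaryote demotion to REVIEW_RARE is applied afterwards over the whole
    genome by :func:`screen_calls` since it depends on the genome-wide
    contaminant total.
    """
    cfg = cfg or ScreenConfig()
    if call.category != "contaminant":
        return None

    host_k = context.declared.kingdom
    host_super = superkingdom(host_k)
    inter_kingdom = call.kingdom != host_k

    if _is_virus_division(call.kingdom):
        if host_super == "prokaryote":
            return None  # all viral elements ignored in prokaryote queries
        if host_super == "eukaryote":
            # only whole-virus sequences are cleaned; chimeric spans ignored
            return "EXCLUDE" if call.whole_sequence and not call.low_confidence else None
        if host_super == "virus":
            # virus queries: report only cross-superkingdom viral assignments
            vh = _virus_superhost(call.division)
            declared_vh = _virus_superhost(context.declared.division)
            if vh == "other" or declared_vh == "other" or vh == declared_vh:
                return None
            return "EXCLUDE" if call.whole_sequence else "REVIEW"

    if call.low_confidence:
        return "REVIEW"

    if call.whole_sequence:
        return "EXCLUDE"

    # chimeric span
    start, end = call.ranges[0]
    span_len = end - start
    if inter_kingdom:
        if call.division in cfg.lgt_source_divisions and host_super == "eukaryote":
            return "INFO"
        terminal = start <= cfg.terminal_margin or end >= call.seq_length - cfg.terminal_margin
        return "TRIM" if terminal else "FIX"
    # intra-kingdom chimeras below the span threshold are ignored
    if span_len >= cfg.chimera_min_span:
        return "REVIEW"
    return None


def screen_calls(
    reports: list[SequenceReport],
    declared_taxid: int,
    declared: Lineage,
    db_division_stats,
    cfg: ScreenConfig | None = None,
) -> tuple[list[ContaminationCall], ScreenContext]:
    """Run the full genome-level calling logic over per-sequence reports."""
    cfg = cfg or ScreenConfig()
    genome_length = sum(r.length for r in reports)
    top_cov = sum(r.top_hit_coverage for r in reports)
    aggregate_coverage = top_cov / genome_length if genome_length else 0.0

    primary, warnings = infer_primary_set(
        reports, declared, aggregate_coverage, db_division_stats, cfg
    )
    aggregates = aggregate_divisions(reports, declared.division, cfg)
    for division in primary:
        aggregates.pop(division, None)
    flagged = flag_contaminant_divisions(aggregates, cfg)

    context = ScreenContext(
        declared_taxid=declared_taxid,
        declared=declared,
        genome_length=genome_length,
        aggregate_coverage=aggregate_coverage,
        primary_divisions=primary,
        flagged_divisions=flagged,
        aggregates=aggregates,
        warnings=warnings,
    )

    all_calls: list[ContaminationCall] = []
    for rep in reports:
        for call in call_sequence(rep, flagged, context, cfg):
            if call.category != "contaminant":
                continue
            action = assign_action(call, context, cfg)
            if action is None:
                continue
            call.action = action
            all_calls.append(call)

    # prokaryote-in-prokaryote: totals at or below the genome fraction
    # threshold are not auto-cleaned
    if superkingdom(declared.kingdom) == "prokaryote" and genome_length:
        pp = [
            c
            for c in all_calls
            if superkingdom(c.kingdom) == "prokaryote" and c.action in CORRECTIVE_ACTIONS
        ]
        total = sum(e - s for c in pp for s, e in c.ranges)
        if total and total / genome_length <= cfg.prok_in_prok_max_fraction:
            for c in pp:
                c.action = "REVIEW_RARE"

    all_calls.sort(key=lambda c: (c.seq_id, c.ranges[0][0] if c.ranges else 0))
    return all_calls, context
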