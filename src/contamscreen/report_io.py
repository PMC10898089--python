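"""Action report writing, FASTA cleaning, and the end-to-end screen.

The action report is a TSV listing contaminant sequence identifiers, their
1-based inclusive ranges, taxonomic assignments, coverage values, and one
of six recommended actions.  EXCLUDE / TRIM / FIX are applied automatically
when cleaning; INFO / REVIEW / REVIEW_RARE never modify the FASTA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import intervals as iv
from .aligner import AlignmentHit, align_contig
from .classifier import ContaminationCall, ScreenContext, screen_calls
from .config import ScreenConfig
from .hashing import encode_sequence
from .hmer_index import GxDatabase, read_fasta, write_fasta
from .preprocess import (
    Contig,
    MaskTrack,
    chunk_contig,
    detect_transposon_hmers,
    mask_low_complexity,
    split_on_n_runs,
)
from .taxonomy import EUKARYOTE_KINGDOMS, summarize_sequence_hits

__all__ = [
    "ActionRecord",
    "ScreenResult",
    "apply_actions",
    "read_action_report",
    "run_screen",
    "write_action_report",
]

logger = logging.getLogger("contamscreen")

REPORT_COLUMNS = [
    "#seq_id",
    "start_pos",
    "end_pos",
    "seq_len",
    "action",
    "div",
    "agg_cont_cov",
    "top_tax_name",
]


@dataclass
class ActionRecord:
    """One row of the action report (1-based inclusive coordinates)."""

    seq_id: str
    start_pos: int
    end_pos: int
    seq_len: int
    action: str
    division: str
    coverage_percent: float
    top_species: str

    def __post_init__(self) -> None:
        if not (1 <= self.start_pos <= self.end_pos <= self.seq_len):
            raise ValueError(
                f"invalid range {self.start_pos}..{self.end_pos} for "
                f"{self.seq_id} of length {self.seq_len}"
            )

    @classmethod
    def from_call(cls, call: ContaminationCall) -> list["ActionRecord"]:
        records = []
        for start, end in call.ranges:
            records.append(
                cls(
                    seq_id=call.seq_id,
                    start_pos=start + 1,
                    end_pos=end,
                    seq_len=call.seq_length,
                    action=call.action or "",
                    division=call.division,
                    coverage_percent=call.coverage_percent,
                    top_species=call.top_species,
                )
            )
        return records


def write_action_report(records: list[ActionRecord], path: str | Path) -> None:
    """Write the TSV action report, sorted by sequence id then start."""
    records = sorted(records, key=lambda r: (r.seq_id, r.start_pos, r.end_pos))
    with open(path, "w") as f:
        f.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in records:
            f.write(
                f"{r.seq_id}\t{r.start_pos}\t{r.end_pos}\t{r.seq_len}\t{r.action}\t"
                f"{r.division}\t{r.coverage_percent:.1f}\t{r.top_species}\n"
            )


def read_action_report(path: str | Path) -> list[ActionRecord]:
    records = []
    with open(path) as f:
        header = f.readline()
        if not header.startswith("#seq_id"):
            raise ValueError(f"{path}: not an action report")
        for line in f:
            parts = line.rstrip("\n").split("\t")
            records.append(
                ActionRecord(
                    seq_id=parts[0],
                    start_pos=int(parts[1]),
                    end_pos=int(parts[2]),
                    seq_len=int(parts[3]),
                    action=parts[4],
                    division=parts[5],
                    coverage_percent=float(parts[6]),
                    top_species=parts[7] if len(parts) > 7 else "",
                )
            )
    return records


def apply_actions(
    records_in: list[tuple[str, str]],
    actions: list[ActionRecord],
    min_seq_len: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Apply corrective actions to FASTA records.

    EXCLUDE removes whole sequences; TRIM removes terminal ranges; FIX
    removes internal ranges, splitting the sequence into suffixed parts
    (".1", ".2", ...).  INFO/REVIEW/REVIEW_RARE leave sequences untouched.
    Removed material goes to the contaminant bin; ``min_seq_len`` drops
    short cleaned sequences (binned as well) last.

    Returns ``(cleaned_records, binned_records)``.
    """
    by_seq: dict[str, list[ActionRecord]] = {}
    for a in actions:
        by_seq.setdefault(a.seq_id, []).append(a)
    for seq_id in by_seq:
        by_seq[seq_id].sort(key=lambda a: (a.start_pos, a.end_pos))

    cleaned: list[tuple[str, str]] = []
    binned: list[tuple[str, str]] = []
    for seq_id, seq in records_in:
        acts = by_seq.get(seq_id, [])
        for a in acts:
            if a.end_pos > len(seq):
                raise ValueError(
                    f"action report range {a.start_pos}..{a.end_pos} exceeds "
                    f"sequence {seq_id} length {len(seq)} (corrupt report?)"
                )
        if any(a.action == "EXCLUDE" for a in acts):
            binned.append((seq_id, seq))
            continue
        removal = iv.merge(
            [(a.start_pos - 1, a.end_pos) for a in acts if a.action in ("TRIM", "FIX")]
        )
        if not removal:
            cleaned.append((seq_id, seq))
            continue
        for s, e in removal:
            binned.append((f"{seq_id}:{s + 1}-{e}", seq[s:e]))
        kept = iv.subtract([(0, len(seq))], removal)
        kept = [(s, e) for s, e in kept if e > s]
        if len(kept) == 1:
            cleaned.append((seq_id, seq[kept[0][0] : kept[0][1]]))
        else:
            for i, (s, e) in enumerate(kept, start=1):
                cleaned.append((f"{seq_id}.{i}", seq[s:e]))

    if min_seq_len:
        survivors = []
        for seq_id, seq in cleaned:
            if len(seq) < min_seq_len:
                binned.append((seq_id, seq))
            else:
                survivors.append((seq_id, seq))
        cleaned = survivors
    return cleaned, binned


@dataclass
class ScreenResult:
    records: list[ActionRecord]
    calls: list[ContaminationCall]
    context: ScreenContext
    reports: list
    cleaned: list[tuple[str, str]]
    binned: list[tuple[str, str]]
    warnings: list[str]


def run_screen(
    fasta: str | Path | list[tuple[str, str]],
    taxid: int,
    db: GxDatabase,
    cfg: ScreenConfig | None = None,
    exclude_taxids: frozenset[int] | set[int] = frozenset(),
    out_dir: str | Path | None = None,
) -> ScreenResult:
    """Screen an assembly against the database and produce the action report.

    Pipeline: split scaffolds on N-runs -> mask repeats and low-complexity
    regions -> two-pass alignment -> per-sequence summaries -> genome-level
    contamination calling -> report + cleaned FASTA.  The declared ``taxid``
    must resolve through the database taxonomy before any alignment starts.

    When ``out_dir`` is given, the report (``contam_report.tsv``), cleaned
    FASTA (``cleaned.fa``) and contaminant bin (``contaminants.fa``) are
    written there.
    """
    cfg = cfg or ScreenConfig()
    declared = db.taxonomy.resolve(taxid)
    exclude_taxids = frozenset(exclude_taxids)

    scaffolds = read_fasta(fasta) if isinstance(fasta, (str, Path)) else list(fasta)
    scaffold_lengths = [len(s) for _, s in scaffolds]
    logger.info("screening %d sequences (%d bp) declared as %s / %s",
                len(scaffolds), sum(scaffold_lengths), declared.species, declared.division)

    contigs: list[Contig] = []
    for seq_id, seq in scaffolds:
        contigs.extend(split_on_n_runs(seq_id, seq, cfg.n_split_min_run))
    logger.info("split into %d contigs", len(contigs))

    encoded: dict[str, tuple] = {}
    for c in contigs:
        codes, filled = encode_sequence(c.sequence, c.contig_id)
        encoded[c.contig_id] = (codes, filled)

    # transposon masking: eukaryote queries only
    is_euk = declared.kingdom in EUKARYOTE_KINGDOMS
    transposon_tracks: dict[str, list] = {c.contig_id: [] for c in contigs}
    if is_euk and cfg.repeat_masking:
        _, transposon_tracks = detect_transposon_hmers(
            [(c.contig_id, encoded[c.contig_id][0]) for c in contigs],
            scaffold_lengths,
            min_count=cfg.transposon_min_count,
            expected_multiple=cfg.transposon_expected_multiple,
        )

    # per-contig masking and alignment
    hits_by_scaffold: dict[str, list[AlignmentHit]] = {sid: [] for sid, _ in scaffolds}
    masks_by_scaffold: dict[str, MaskTrack] = {sid: MaskTrack() for sid, _ in scaffolds}
    for c in contigs:
        codes, filled = encoded[c.contig_id]
        lc = mask_low_complexity(codes, threshold=cfg.entropy_threshold)
        tx = transposon_tracks.get(c.contig_id, [])
        track = masks_by_scaffold[c.scaffold_id]
        track.low_complexity.extend((s + c.offset, e + c.offset) for s, e in lc)
        track.transposon.extend((s + c.offset, e + c.offset) for s, e in tx)

        spans = [(ch.start, ch.end) for ch in chunk_contig(c, cfg.chunk_size, cfg.chunk_overlap)]
        hits, _stats = align_contig(
            c.scaffold_id, codes, filled, spans, db, cfg,
            seed_mask_intervals=iv.merge(lc + tx),
            exclude_taxids=exclude_taxids,
        )
        # lift to scaffold coordinates
        for h in hits:
            h.q_start += c.offset
            h.q_end += c.offset
            h.segments = [(q + c.offset, ln) for q, ln in h.segments]
        hits_by_scaffold[c.scaffold_id].extend(hits)

    logger.info("alignment produced %d hits", sum(map(len, hits_by_scaffold.values())))

    reports = []
    for seq_id, seq in scaffolds:
        track = masks_by_scaffold[seq_id]
        reports.append(
            summarize_sequence_hits(
                seq_id,
                len(seq),
                hits_by_scaffold[seq_id],
                db.taxonomy,
                declared.kingdom,
                low_complexity=track.low_complexity,
                transposon=track.transposon,
            )
        )

    calls, context = screen_calls(reports, taxid, declared, db.division_stats(), cfg)
    records = [r for call in calls for r in ActionRecord.from_call(call)]
    cleaned, binned = apply_actions(scaffolds, records, cfg.min_seq_len)
    logger.info("%d action records; %d sequences kept, %d binned",
                len(records), len(cleaned), len(binned))

    for w in context.warnings:
        logger.warning("%s", w)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_action_report(records, out_dir / "contam_report.tsv")
        write_fasta(out_dir / "cleaned.fa", cleaned)
        write_fasta(out_dir / "contaminants.fa", binned)

    return ScreenResult(
        records=records,
        calls=calls,
        context=context,
        reports=reports,
        cleaned=cleaned,
        binned=binned,
        warnings=context.warnings,
    )
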