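"""Taxonomic lineages, per-sequence hit summaries, and conserved intervals.

The screen classifies at two coarse ranks above species:

* **division** — the unit at which contamination is assigned, named
  ``<kingdom-prefix>:<group>`` (e.g. ``anml:primates``);
* **kingdom** — one of eight top groups: Metazoa, Viridiplantae, Fungi,
  other-Eukaryota, Bacteria, Archaea, Viruses, Synthetic.

A miniature taxonomy table ships with the package; users supply their own
table as a TSV with columns ``taxid, species, division, kingdom``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from . import intervals as iv
from .intervals import Interval

__all__ = [
    "KINGDOMS",
    "EUKARYOTE_KINGDOMS",
    "PROKARYOTE_KINGDOMS",
    "Lineage",
    "TaxonomyTable",
    "SequenceReport",
    "conserved_intervals",
    "default_table",
    "summarize_sequence_hits",
    "superkingdom",
]

EUKARYOTE_KINGDOMS = frozenset({"Metazoa", "Viridiplantae", "Fungi", "other-Eukaryota"})
PROKARYOTE_KINGDOMS = frozenset({"Bacteria", "Archaea"})
KINGDOMS = EUKARYOTE_KINGDOMS | PROKARYOTE_KINGDOMS | {"Viruses", "Synthetic"}

#: conventional division-name prefix per kingdom
KINGDOM_PREFIX = {
    "Metazoa": "anml",
    "Viridiplantae": "plnt",
    "Fungi": "fung",
    "other-Eukaryota": "prot",
    "Bacteria": "prok",
    "Archaea": "arch",
    "Viruses": "virs",
    "Synthetic": "synt",
}

VIRUS_DIVISIONS = {
    "prokaryote": "virs:prokaryotic viruses",
    "eukaryote": "virs:eukaryotic viruses",
    "other": "virs:other viruses",
}


def superkingdom(kingdom: str) -> str:
    """Collapse the eight kingdoms to eukaryote / prokaryote / virus / other."""
    if kingdom in EUKARYOTE_KINGDOMS:
        return "eukaryote"
    if kingdom in PROKARYOTE_KINGDOMS:
        return "prokaryote"
    if kingdom == "Viruses":
        return "virus"
    return "other"


class Lineage(NamedTuple):
    species: str
    division: str
    kingdom: str


class TaxonomyTable:
    """Maps taxids to (species, division, kingdom).

    Every database sequence's taxid must resolve to exactly one division and
    one kingdom; unknown taxids are a hard error.
    """

    COLUMNS = ["taxid", "species", "division", "kingdom"]

    def __init__(self, rows: pd.DataFrame):
        df = rows[self.COLUMNS].copy()
        df["taxid"] = df["taxid"].astype(int)
        bad = set(df["kingdom"]) - KINGDOMS
        if bad:
            raise ValueError(f"unknown kingdoms in taxonomy table: {sorted(bad)}")
        if df["taxid"].duplicated().any():
            dups = df.loc[df["taxid"].duplicated(), "taxid"].tolist()
            raise ValueError(f"duplicate taxids in taxonomy table: {dups}")
        self.df = df.reset_index(drop=True)
        self._by_taxid = {
            int(t): Lineage(s, d, k)
            for t, s, d, k in zip(df["taxid"], df["species"], df["division"], df["kingdom"])
        }

    def __contains__(self, taxid: int) -> bool:
        return int(taxid) in self._by_taxid

    def __len__(self) -> int:
        return len(self._by_taxid)

    def resolve(self, taxid: int) -> Lineage:
        try:
            return self._by_taxid[int(taxid)]
        except KeyError:
            raise KeyError(
                f"taxid {taxid} not present in the taxonomy table; add a row "
                f"(taxid, species, division, kingdom) for it or pass the correct table"
            ) from None

    def division_kingdom(self, division: str) -> str:
        hits = self.df.loc[self.df["division"] == division, "kingdom"]
        if hits.empty:
            raise KeyError(f"division {division!r} not present in the taxonomy table")
        return hits.iloc[0]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def merged_with(self, other: "TaxonomyTable") -> "TaxonomyTable":
        df = pd.concat([self.df, other.df]).drop_duplicates(subset="taxid")
        return TaxonomyTable(df)


def default_table() -> TaxonomyTable:
    """The miniature taxonomy shipped with the package (example taxa only)."""
    rows = [
        (9606, "Homo sapiens", "anml:primates", "Metazoa"),
        (10090, "Mus musculus", "anml:rodents", "Metazoa"),
        (7227, "Drosophila melanogaster", "anml:insects", "Metazoa"),
        (562, "Escherichia coli", "prok:g-proteobacteria", "Bacteria"),
        (953, "Wolbachia pipientis", "prok:a-proteobacteria", "Bacteria"),
        (2242, "Halobacterium salinarum", "arch:euryarchaeotes", "Archaea"),
        (4932, "Saccharomyces cerevisiae", "fung:ascomycetes", "Fungi"),
        (3702, "Arabidopsis thaliana", "plnt:eudicots", "Viridiplantae"),
        (4530, "Oryza sativa", "plnt:monocots", "Viridiplantae"),
        (5833, "Plasmodium falciparum", "prot:apicomplexans", "other-Eukaryota"),
        (10847, "Escherichia phage phiX174", VIRUS_DIVISIONS["prokaryote"], "Viruses"),
        (10376, "Epstein-Barr virus", VIRUS_DIVISIONS["eukaryote"], "Viruses"),
        (32630, "synthetic construct", "synt:synthetic", "Synthetic"),
    ]
    return TaxonomyTable(pd.DataFrame(rows, columns=TaxonomyTable.COLUMNS))


def resolve_lineage(taxid: int, table: TaxonomyTable) -> Lineage:
    """Resolve a taxid to its (species, division, kingdom) lineage."""
    return table.resolve(taxid)


@dataclass
class SpeciesSummary:
    taxid: int
    species: str
    division: str
    kingdom: str
    intervals: list[Interval]
    coverage: int
    score: float
    segment_sq_sum: float


@dataclass
class DivisionSummary:
    division: str
    kingdom: str
    intervals: list[Interval]
    coverage: int
    score: float
    low_complexity_bp: int = 0
    transposon_bp: int = 0
    conserved_bp: int = 0

    @property
    def repeat_conserved_bp(self) -> int:
        # low-complexity/conserved and transposon spans may overlap; cap at
        # total coverage
        return min(self.coverage, self.low_complexity_bp + self.conserved_bp + self.transposon_bp)


@dataclass
class SequenceReport:
    """Per-query-sequence hit summary under the reporting limits.

    ``retained`` lists at most four species overall and at most two per
    division (ranked by score); per-division aggregates are computed from all
    hits regardless of the species-reporting caps.
    """

    seq_id: str
    length: int
    species: dict[int, SpeciesSummary] = field(default_factory=dict)
    retained: list[int] = field(default_factory=list)
    divisions: dict[str, DivisionSummary] = field(default_factory=dict)
    conserved: list[Interval] = field(default_factory=list)
    low_complexity: list[Interval] = field(default_factory=list)
    transposon: list[Interval] = field(default_factory=list)
    top_hit_coverage: int = 0

    @property
    def has_hits(self) -> bool:
        return bool(self.species)


def conserved_intervals(
    division_tracks: dict[str, list[Interval]], query_kingdom: str, min_divisions: int = 5
) -> list[Interval]:
    """Base positions covered by alignments from >= 5 distinct divisions.

    Highly conserved intervals are computed only for eukaryote queries;
    prokaryote and virus queries always yield an empty set.
    """
    if query_kingdom not in EUKARYOTE_KINGDOMS:
        return []
    return iv.covered_by_at_least(list(division_tracks.values()), min_divisions)


def summarize_sequence_hits(
    seq_id: str,
    length: int,
    hits: list,
    taxonomy: TaxonomyTable,
    query_kingdom: str,
    low_complexity: list[Interval] | None = None,
    transposon: list[Interval] | None = None,
    max_species: int = 4,
    max_per_division: int = 2,
) -> SequenceReport:
    """Aggregate alignment hits for one query sequence into a report.

    ``hits`` are :class:`~contamscreen.aligner.AlignmentHit` objects in query
    coordinates of this sequence.  Species coverage is the length of the
    union of their query intervals; species are ranked by score with a taxid
    tie-break, then truncated to the reporting caps.
    """
    low_complexity = iv.merge(low_complexity or [])
    transposon = iv.merge(transposon or [])
    rep = SequenceReport(
        seq_id=seq_id, length=length, low_complexity=low_complexity, transposon=transposon
    )

    by_species: dict[int, list] = {}
    for h in hits:
        by_species.setdefault(h.taxid, []).append(h)

    for taxid, shits in by_species.items():
        lin = taxonomy.resolve(taxid)
        ivs = iv.merge([(h.q_start, h.q_end) for h in shits])
        sq = float(sum(ln * ln for h in shits for ln in h.identity_segments))
        rep.species[taxid] = SpeciesSummary(
            taxid=taxid,
            species=lin.species,
            division=lin.division,
            kingdom=lin.kingdom,
            intervals=ivs,
            coverage=min(iv.total_length(ivs), length),
            score=sq**0.5,
            segment_sq_sum=sq,
        )

    # reporting caps: <=4 species overall, <=2 per division
    ranked = sorted(rep.species.values(), key=lambda s: (-s.score, s.taxid))
    per_div: dict[str, int] = {}
    for s in ranked:
        if len(rep.retained) >= max_species:
            break
        if per_div.get(s.division, 0) >= max_per_division:
            continue
        per_div[s.division] = per_div.get(s.division, 0) + 1
        rep.retained.append(s.taxid)

    # per-division aggregates from all hits (caps govern reporting only)
    div_tracks: dict[str, list[Interval]] = {}
    div_sq: dict[str, float] = {}
    div_kingdom: dict[str, str] = {}
    for s in rep.species.values():
        div_tracks.setdefault(s.division, []).extend(s.intervals)
        div_sq[s.division] = div_sq.get(s.division, 0.0) + s.segment_sq_sum
        div_kingdom[s.division] = s.kingdom

    rep.conserved = conserved_intervals(div_tracks, query_kingdom)

    for division, track in div_tracks.items():
        merged = iv.merge(track)
        rep.divisions[division] = DivisionSummary(
            division=division,
            kingdom=div_kingdom[division],
            intervals=merged,
            coverage=min(iv.total_length(merged), length),
            score=div_sq[division] ** 0.5,
            low_complexity_bp=iv.intersect_length(merged, low_complexity),
            transposon_bp=iv.intersect_length(merged, transposon),
            conserved_bp=iv.intersect_length(merged, rep.conserved),
        )

    if rep.retained:
        top = [ivl for t in rep.retained for ivl in rep.species[t].intervals]
        rep.top_hit_coverage = min(iv.total_length(top), length)
    return rep
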