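"""Screen configuration: every tunable threshold in one place.

Defaults follow the published calling rules where a printed value exists
(aggregate score filter 150, coverage filter 80%, the 75% repeat/overlap
criteria, 10-kbp non-repetitive minimum, per-sequence scores 50/100, 50%
repeat content, coverage cutoff 0.2 floor / 0.6 slope, 10-kbp intra-kingdom
chimera span, 1% prokaryote-in-prokaryote fraction).  The remaining knobs
are implementation choices documented in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

__all__ = ["ScreenConfig"]


@dataclass
class ScreenConfig:
    # --- pass 1 ---------------------------------------------------------
    query_stride: int = 1  #: query h-mer sampling stride (db side uses 10/20)
    noise_diag_bp: int = 1_000  #: seed noise filter: diagonal neighbourhood
    noise_antidiag_bp: int = 10_000  #: seed noise filter: antidiagonal neighbourhood
    pass1_merge_gap: int = 1_000  #: same-diagonal seeds merged into runs within this gap
    top_taxa_per_metric: int = 3  #: pass-2 taxa: top-N under each of four metrics

    # --- pass 2 ---------------------------------------------------------
    neighborhood_cap: int = 100_000  #: subject neighbourhood = min(cap, 2 x query len)
    xdrop: int = 20  #: ungapped extension drop-off (match +1, mismatch -2)
    gap_band: int = 25  #: indels sought within +/- this many bp of the alignment end
    gap_scan: int = 60  #: window scanned for a continuation seed past the end
    min_gap_segment: int = 8  #: significant ungapped continuation: >= this many exact bp
    seed_group_gap: int = 60  #: pass-2 seeds chained on a diagonal within this q-gap
    min_seeds_per_group: int = 2  #: diagonal groups smaller than this are noise
    max_anchors: int = 500  #: extension anchors per subject neighbourhood
    min_hit_span: int = 30  #: discard refined hits shorter than this
    min_hit_segment: int = 18  #: a hit must contain one exact run this long
    #: (random 20-bit seed chains almost never do; real alignments at any
    #: plausible divergence always do)
    mask_seeds: bool = True  #: exclude masked windows from seeding (extension still crosses)

    # --- preprocessing --------------------------------------------------
    n_split_min_run: int = 10
    chunk_size: int = 100_000
    chunk_overlap: int = 100
    entropy_threshold: float = 4.5
    transposon_min_count: int = 10
    transposon_expected_multiple: float = 5.0
    repeat_masking: bool = True  #: transposon masking (eukaryote queries only)

    # --- classifier -----------------------------------------------------
    aggregate_min_score: float = 150.0  #: alignments below this are filtered out
    aggregate_min_coverage: float = 0.8  #: keep alignments covering > this fraction
    repeat_fraction_criterion: float = 0.75  #: criteria (a), (b), (d) threshold
    min_nonrepetitive_bp: int = 10_000  #: criterion (c)
    flagged_min_score: float = 50.0  #: per-sequence score for flagged divisions
    interkingdom_min_coverage: float = 0.8  #: alt. per-sequence rule, inter-kingdom
    unflagged_min_score: float = 100.0  #: per-sequence score for unflagged divisions
    unflagged_max_repeat_content: float = 0.5
    coverage_cutoff_floor: float = 0.2
    coverage_cutoff_slope: float = 0.6
    chimera_min_span: int = 10_000  #: intra-kingdom chimeras below this are ignored
    prok_in_prok_max_fraction: float = 0.01  #: <= this fraction -> REVIEW_RARE
    terminal_margin: int = 100  #: span reaching this close to an end is terminal (TRIM)
    chimera_join_gap: int = 1_000  #: contaminant intervals joined across gaps this size
    min_primary_anchor_bp: int = 1_000  #: below this primary coverage a call is whole-sequence
    concordance_ceiling: float = 0.75  #: primary-set overlap threshold at full coverage
    concordance_floor: float = 0.5  #: ... and its minimum for poorly covered genomes
    well_represented_min_seqs: int = 1  #: declared-division representation for the
    well_represented_min_bp: int = 50_000  #: wrong-taxid warning (desk-scale defaults)
    conserved_min_divisions: int = 5
    lgt_source_divisions: tuple[str, ...] = ("prok:a-proteobacteria",)  #: endosymbiont defaults

    # --- output ---------------------------------------------------------
    min_seq_len: int = 0  #: drop cleaned sequences below this length (0 = keep all)

    def replace(self, **kwargs) -> "ScreenConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreenConfig":
        """Load overrides from JSON or simple ``key=value`` lines."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ScreenConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for key, value in data.items():
            if key not in types:
                raise KeyError(f"unknown config key: {key}")
            default = getattr(defaults, key)
            if isinstance(default, bool):
                value = value in (True, "true", "True", "1", 1)
            elif isinstance(default, int):
                value = int(value)
            elif isinstance(default, float):
                value = float(value)
            elif isinstance(default, tuple):
                if isinstance(value, str):
                    value = tuple(v.strip() for v in value.split(",") if v.strip())
                else:
                    value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)
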