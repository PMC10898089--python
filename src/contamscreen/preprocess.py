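"""Query pre-processing: contig splitting, chunking, and repeat masking.

Scaffolds are split into contigs at N-runs of 10 bp or longer (shorter runs
are retained and pseudorandom-filled before hashing).  Contigs are chunked
into 100-kbp pieces with a 100-bp overlap so alignment memory stays bounded;
chunk alignments are later recombined as if the contig was aligned whole.

Two intra-genome repeat classes are masked in queries because they generate
cross-division alignment noise: low-complexity sequence (hexamer Shannon
entropy below 4.5 bits in a 50-bp sliding window) and, in eukaryotes,
transposon-like repeats detected as overrepresented h-mers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv
from .hashing import DB_HMER, HmerSpec, encode_sequence
from .hmer_index import hmer_positions
from .intervals import Interval

__all__ = [
    "Chunk",
    "Contig",
    "MaskTrack",
    "chunk_contig",
    "detect_transposon_hmers",
    "mask_low_complexity",
    "split_on_n_runs",
]

N_SPLIT_MIN_RUN = 10
CHUNK_SIZE = 100_000
CHUNK_OVERLAP = 100

ENTROPY_WINDOW = 50
ENTROPY_WORD = 6
ENTROPY_THRESHOLD = 4.5


@dataclass
class Contig:
    """A gap-free piece of a scaffold (no N-run >= the split threshold)."""

    scaffold_id: str
    contig_index: int
    offset: int  # 0-based offset within the scaffold
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def contig_id(self) -> str:
        return f"{self.scaffold_id}~{self.contig_index}"


@dataclass
class Chunk:
    contig: Contig
    start: int  # 0-based within the contig, half-open end
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MaskTrack:
    """Per-sequence mask interval sets (sorted, non-overlapping, clipped)."""

    low_complexity: list[Interval] = field(default_factory=list)
    transposon: list[Interval] = field(default_factory=list)
    conserved: list[Interval] = field(default_factory=list)

    def seed_mask(self) -> list[Interval]:
        return iv.merge(self.low_complexity + self.transposon)


def split_on_n_runs(
    scaffold_id: str, sequence: str, min_run: int = N_SPLIT_MIN_RUN
) -> list[Contig]:
    """Split a scaffold at every maximal N-run of length >= ``min_run``.

    Shorter N-runs are retained inside contigs (they are pseudorandom-filled
    downstream).  Empty fragments are discarded; an all-N scaffold yields no
    contigs.
    """
    contigs: list[Contig] = []
    upper = sequence.upper()
    pos = 0
    idx = 0
    start = 0  # start of current fragment
    n = len(sequence)
    while pos < n:
        if upper[pos] == "N":
            run_start = pos
            while pos < n and upper[pos] == "N":
                pos += 1
            if pos - run_start >= min_run:
                if run_start > start:
                    contigs.append(Contig(scaffold_id, idx, start, sequence[start:run_start]))
                    idx += 1
                start = pos
        else:
            pos += 1
    if n > start:
        contigs.append(Contig(scaffold_id, idx, start, sequence[start:n]))
    return contigs


def chunk_contig(
    contig: Contig, chunk_size: int = CHUNK_SIZE, overlap: int = CHUNK_OVERLAP
) -> list[Chunk]:
    """Chunk a contig into <= ``chunk_size`` pieces overlapping by ``overlap``.

    Chunk starts step by ``chunk_size - overlap``; a contig no longer than
    one chunk yields a single chunk covering it entirely.
    """
    step = chunk_size - overlap
    n = contig.length
    chunks = [Chunk(contig, 0, min(chunk_size, n))]
    while chunks[-1].end < n:
        s = chunks[-1].start + step
        chunks.append(Chunk(contig, s, min(s + chunk_size, n)))
    return chunks


_CLOG: np.ndarray | None = None


def _c_log_c(limit: int) -> np.ndarray:
    global _CLOG
    if _CLOG is None or len(_CLOG) < limit + 1:
        c = np.arange(max(limit + 1, 64), dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            _CLOG = np.where(c > 0, c * np.log2(np.maximum(c, 1)), 0.0)
    return _CLOG


def hexamer_entropy(codes: np.ndarray, word: int = ENTROPY_WORD) -> float:
    """Shannon entropy (bits) of the hexamer distribution of one window."""
    n_words = len(codes) - word + 1
    if n_words <= 0:
        return math.inf
    ids = np.zeros(n_words, dtype=np.int64)
    for j in range(word):
        ids = (ids << 2) | codes[j : j + n_words]
    counts = np.unique(ids, return_counts=True)[1]
    p = counts / n_words
    return float(-(p * np.log2(p)).sum())


def mask_low_complexity(
    sequence: str | np.ndarray,
    window: int = ENTROPY_WINDOW,
    word: int = ENTROPY_WORD,
    threshold: float = ENTROPY_THRESHOLD,
) -> list[Interval]:
    """Low-complexity intervals by sliding-window hexamer entropy.

    A 50-bp window holds 45 overlapping hexamers; windows whose hexamer
    Shannon entropy falls below 4.5 bits are marked and merged into maximal
    intervals.  The window steps by 1 bp.  A sequence shorter than one
    window is evaluated as a single full-length window when it holds at
    least one hexamer; shorter sequences are never masked.
    """
    if isinstance(sequence, str):
        codes, _ = encode_sequence(sequence, "mask")
    else:
        codes = sequence
    n = len(codes)
    if n < word:
        return []
    if n < window:
        return [(0, n)] if hexamer_entropy(codes, word) < threshold else []

    n_words_total = n - word + 1
    ids = np.zeros(n_words_total, dtype=np.int64)
    for j in range(word):
        ids = (ids << 2) | codes[j : j + n_words_total]

    w_words = window - word + 1  # hexamers per window (45)
    clog = _c_log_c(w_words)
    log_w = math.log2(w_words)

    counts: dict[int, int] = {}
    s = 0.0  # sum of c*log2(c) over hexamer counts in the window
    for k in ids[:w_words]:
        c = counts.get(k, 0)
        s += clog[c + 1] - clog[c]
        counts[k] = c + 1

    below: list[bool] = [log_w - s / w_words < threshold]
    for i in range(1, n - window + 1):
        out_id = ids[i - 1]
        in_id = ids[i + w_words - 1]
        if out_id != in_id:
            c = counts[out_id]
            s += clog[c - 1] - clog[c]
            if c == 1:
                del counts[out_id]
            else:
                counts[out_id] = c - 1
            c = counts.get(in_id, 0)
            s += clog[c + 1] - clog[c]
            counts[in_id] = c + 1
        below.append(log_w - s / w_words < threshold)

    marked = [(i, i + window) for i, b in enumerate(below) if b]
    return iv.merge(marked)


def scaffold_n80(scaffold_lengths: list[int]) -> int:
    """N80 of scaffold lengths (length at which cumulative coverage >= 80%)."""
    if not scaffold_lengths:
        return 0
    lens = sorted(scaffold_lengths, reverse=True)
    target = 0.8 * sum(lens)
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= target:
            return ln
    return lens[-1]


def detect_transposon_hmers(
    contigs: list[tuple[str, np.ndarray]],
    scaffold_lengths: list[int],
    spec: HmerSpec = DB_HMER,
    min_count: int = 10,
    expected_multiple: float = 5.0,
) -> tuple[np.ndarray, dict[str, list[Interval]]]:
    """Flag overrepresented h-mers and derive per-contig transposon intervals.

    h-mer frequency statistics are computed only over contigs of length at
    least ``min(100 kbp, scaffold N80 before N-splitting)`` so that a genome
    made of many short similar sequences (egregious contamination rather
    than real transposons) contributes nothing.  h-mers whose genome-wide
    count exceeds ``max(min_count, expected_multiple x expected count under
    uniform sampling)`` are flagged; query positions covered by flagged
    h-mer windows become transposon intervals on every contig.

    The caller is responsible for skipping this step for prokaryote and
    virus queries, where transposon masking is not used.
    """
    scope = min(100_000, scaffold_n80(scaffold_lengths))
    key_parts = []
    total = 0
    for _cid, codes in contigs:
        if len(codes) < scope:
            continue
        _, keys, _ = hmer_positions(codes, 1, spec)
        key_parts.append(keys)
        total += len(keys)
    if not key_parts:
        return np.array([], dtype=np.uint64), {cid: [] for cid, _ in contigs}

    all_keys = np.concatenate(key_parts)
    uniq, counts = np.unique(all_keys, return_counts=True)
    expected = total / float(1 << spec.hash_bits)
    cutoff = max(min_count, expected_multiple * expected)
    flagged = uniq[counts > cutoff]

    tracks: dict[str, list[Interval]] = {}
    for cid, codes in contigs:
        starts, keys, _ = hmer_positions(codes, 1, spec)
        if len(starts) == 0 or len(flagged) == 0:
            tracks[cid] = []
            continue
        hit = flagged[np.searchsorted(flagged, keys).clip(max=len(flagged) - 1)] == keys
        pos = starts[hit]
        tracks[cid] = iv.merge([(int(p), int(p) + spec.window) for p in pos])
    return flagged, tracks
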