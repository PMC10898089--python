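"""Two-pass seed-and-extend cross-species alignment against the h-mer index.

Pass 1 looks up every query h-mer in the reference index, filters spurious
seeds with a diagonal/antidiagonal neighbour test, merges survivors into
ungapped runs and ranks taxa by four per-taxon metrics (count, maximum
length, summed length, summed squared length).  Taxa in the top three of
any metric proceed to pass 2.

Pass 2 builds an on-the-fly index of the query with smaller (20-bit) h-mers
and scans subject neighbourhoods around the pass-1 loci against it.  Seeds
are extended ungapped with an x-drop rule, then gapped by repeatedly taking
the indel near the alignment end whose continuation yields the longest
exact run.  The alignment score is the square root of the sum of squared
100%-identity segment lengths, which down-weights clustered mismatches
relative to the same number of matches in one unbroken run.

Coordinates: query positions are plain 0-based; subject positions in seeds
are signed so that the noise-filter inequalities apply uniformly to both
orientations (``s_signed = orient * (s + 1)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScreenConfig
from .hashing import QUERY_HMER
from .hmer_index import GxDatabase, hmer_positions
from .intervals import Interval

__all__ = [
    "AlignmentHit",
    "Pass1Run",
    "Pass1TaxonStats",
    "align_contig",
    "run_pass1",
    "run_pass2",
    "score_alignment",
    "select_taxa",
]


def score_alignment(identity_segments: list[int]) -> float:
    """sqrt of the sum of squared 100%-identity segment lengths.

    An empty segment list scores 0.  Splitting a segment always lowers the
    score (strict subadditivity of the L2 form), so clustered mismatches
    cost more than the same matches unbroken.
    """
    return float(np.sqrt(sum(float(l) * l for l in identity_segments)))


@dataclass
class Pass1Run:
    """An ungapped run of filtered pass-1 seeds on one diagonal."""

    subject_ordinal: int
    taxid: int
    orientation: int  # +1 same strand, -1 opposite
    diagonal: int  # q - s_signed
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class Pass1TaxonStats:
    n_ungapped: int = 0
    max_len: int = 0
    sum_len: int = 0
    sum_sq_len: int = 0

    def add(self, length: int) -> None:
        self.n_ungapped += 1
        self.max_len = max(self.max_len, length)
        self.sum_len += length
        self.sum_sq_len += length * length


@dataclass
class AlignmentHit:
    """A refined pass-2 alignment with its identity segments and score."""

    seq_id: str
    q_start: int
    q_end: int
    subject_ordinal: int
    s_start: int
    s_end: int
    orientation: int
    segments: list[tuple[int, int]]  # (q_pos, length) of 100%-identity runs
    taxid: int
    division: str = ""
    kingdom: str = ""
    species: str = ""
    low_complexity_frac: float = 0.0
    transposon_frac: float = 0.0
    conserved_frac: float = 0.0

    @property
    def identity_segments(self) -> list[int]:
        return [l for _, l in self.segments]

    @property
    def score(self) -> float:
        return score_alignment(self.identity_segments)

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


def _expand_spans(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten [lo, hi) spans into node indices plus the owning span index."""
    counts = (hi - lo).astype(np.int64)
    total = int(counts.sum())
    owner = np.repeat(np.arange(len(lo), dtype=np.int64), counts)
    if total == 0:
        return np.array([], dtype=np.int64), owner
    # index = lo[owner] + within-span offset
    offs = np.arange(total, dtype=np.int64) - np.repeat(
        np.concatenate([[0], np.cumsum(counts)[:-1]]), counts
    )
    return lo[owner] + offs, owner


def _mask_bool(intervals: list[Interval], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s) : min(length, e)] = True
    return mask


def _noise_filter(
    ordinals: np.ndarray, d: np.ndarray, a: np.ndarray, cfg: ScreenConfig
) -> np.ndarray:
    """Keep seeds with a close neighbour: |dd| <= 1 kbp and |da| <= 10 kbp.

    Seeds are binned on a (diagonal, antidiagonal) grid per subject.  Any
    two seeds sharing a cell satisfy both bounds by construction; seeds
    alone in their cell are checked against the eight neighbouring cells.
    """
    if len(d) == 0:
        return np.zeros(0, dtype=bool)
    cd = d // cfg.noise_diag_bp
    ca = a // cfg.noise_antidiag_bp
    cells = np.stack([ordinals, cd, ca], axis=1)
    _, inverse, counts = np.unique(cells, axis=0, return_inverse=True, return_counts=True)
    keep = counts[inverse] >= 2

    lonely = np.nonzero(~keep)[0]
    if len(lonely):
        index: dict[tuple[int, int, int], list[int]] = {}
        for i, key in enumerate(map(tuple, cells)):
            index.setdefault(key, []).append(i)
        for i in lonely:
            o, x, y = cells[i]
            di, ai = d[i], a[i]
            found = False
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    if dx == 0 and dy == 0:
                        continue
                    for j in index.get((o, x + dx, y + dy), ()):
                        if (
                            abs(int(d[j]) - int(di)) <= cfg.noise_diag_bp
                            and abs(int(a[j]) - int(ai)) <= cfg.noise_antidiag_bp
                        ):
                            found = True
                            break
                    if found:
                        break
                if found:
                    break
            keep[i] = found
    return keep


def run_pass1(
    chunk_codes: np.ndarray,
    chunk_offset: int,
    db: GxDatabase,
    cfg: ScreenConfig,
    seed_mask: np.ndarray | None = None,
    exclude_taxids: frozenset[int] = frozenset(),
) -> tuple[list[Pass1Run], dict[int, Pass1TaxonStats]]:
    """Seed one query chunk against the full database and build filtered runs.

    Returns the ungapped runs (after the per-taxon best-overlap filter) in
    contig coordinates, and the per-taxon pass-1 metrics computed from them.
    """
    spec = db.spec
    starts, keys, orient = hmer_positions(chunk_codes, cfg.query_stride, spec)
    if len(starts) == 0:
        return [], {}

    if seed_mask is not None and cfg.mask_seeds:
        mid = starts + spec.window // 2
        ok = ~seed_mask[np.minimum(mid, len(seed_mask) - 1)]
        starts, keys, orient = starts[ok], keys[ok], orient[ok]
    if len(starts) == 0:
        return [], {}

    lo, hi = db.lookup_batch(keys)
    idx, owner = _expand_spans(lo, hi)
    if len(idx) == 0:
        return [], {}

    nodes = db.nodes[idx]
    q = starts[owner] + chunk_offset
    qo = orient[owner].astype(np.int64)
    so = np.sign(nodes["pos"]).astype(np.int64)
    s0 = np.abs(nodes["pos"]).astype(np.int64) - 1
    rel = qo * so
    s_signed = rel * (s0 + 1)
    ordinals = nodes["ordinal"].astype(np.int64)

    if exclude_taxids:
        taxids = db.seq_taxids[ordinals]
        ok = ~np.isin(taxids, np.array(sorted(exclude_taxids), dtype=np.int64))
        q, rel, s_signed, ordinals, s0 = q[ok], rel[ok], s_signed[ok], ordinals[ok], s0[ok]
    if len(q) == 0:
        return [], {}

    d = q - s_signed
    a = q + s_signed
    keep = _noise_filter(ordinals, d, a, cfg)
    q, rel, ordinals, d, s0 = q[keep], rel[keep], ordinals[keep], d[keep], s0[keep]
    if len(q) == 0:
        return [], {}

    # merge same-diagonal survivors into ungapped runs
    order = np.lexsort((q, d, rel, ordinals))
    q, rel, ordinals, d = q[order], rel[order], ordinals[order], d[order]
    taxid_of = db.seq_taxids

    runs: list[Pass1Run] = []
    i = 0
    n = len(q)
    w = spec.window
    while i < n:
        j = i + 1
        while (
            j < n
            and ordinals[j] == ordinals[i]
            and rel[j] == rel[i]
            and d[j] == d[i]
            and q[j] - q[j - 1] <= cfg.pass1_merge_gap
        ):
            j += 1
        q_lo, q_hi = int(q[i]), int(q[j - 1]) + w
        di = int(d[i])
        if rel[i] > 0:
            s_lo, s_hi = q_lo - di - 1, q_hi - di - 1
        else:
            s_lo, s_hi = di - (q_hi - w) - 1, di - q_lo - 1 + w
        runs.append(
            Pass1Run(
                subject_ordinal=int(ordinals[i]),
                taxid=int(taxid_of[ordinals[i]]),
                orientation=int(rel[i]),
                diagonal=di,
                q_start=q_lo,
                q_end=q_hi,
                s_start=s_lo,
                s_end=s_hi,
            )
        )
        i = j

    # per-taxon, keep only the best (longest) among runs overlapping on query
    by_taxon: dict[int, list[Pass1Run]] = {}
    for r in runs:
        by_taxon.setdefault(r.taxid, []).append(r)

    kept_runs: list[Pass1Run] = []
    stats: dict[int, Pass1TaxonStats] = {}
    for taxid, trs in by_taxon.items():
        trs.sort(key=lambda r: (-r.length, r.q_start, r.subject_ordinal))
        kept: list[Pass1Run] = []
        for r in trs:
            if not any(r.q_start < k.q_end and k.q_start < r.q_end for k in kept):
                kept.append(r)
        st = stats.setdefault(taxid, Pass1TaxonStats())
        for r in kept:
            st.add(r.length)
        kept_runs.extend(kept)

    return kept_runs, stats


def select_taxa(stats: dict[int, Pass1TaxonStats], top_n: int = 3) -> set[int]:
    """Union of the top-N taxa under each of the four pass-1 metrics.

    Ties break on taxid so repeated runs select identically.
    """
    selected: set[int] = set()
    for metric in ("n_ungapped", "max_len", "sum_len", "sum_sq_len"):
        ranked = sorted(stats.items(), key=lambda kv: (-getattr(kv[1], metric), kv[0]))
        selected.update(t for t, _ in ranked[:top_n])
    return selected


# ---------------------------------------------------------------------------
# pass 2: extension machinery


def _xdrop_extend(
    qc: np.ndarray,
    sc: np.ndarray,
    qbad: np.ndarray,
    sbad: np.ndarray,
    q0: int,
    s0: int,
    xdrop: int,
    block: int = 512,
) -> int:
    """Length of the best-scoring ungapped extension right from (q0, s0).

    Scoring is +1 match / -2 mismatch; extension stops when the running
    score falls ``xdrop`` below its maximum.  Pseudorandom-filled positions
    count as mismatches.  The returned length includes position 0.
    """
    n = min(len(qc) - q0, len(sc) - s0)
    if n <= 0:
        return 0
    best_val = 0
    best_len = 0
    score = 0
    off = 0
    while off < n:
        end = min(off + block, n)
        m = qc[q0 + off : q0 + end] == sc[s0 + off : s0 + end]
        bad = qbad[q0 + off : q0 + end] | sbad[s0 + off : s0 + end]
        vals = np.where(m & ~bad, 1, -2)
        cum = score + np.cumsum(vals)
        runmax = np.maximum(np.maximum.accumulate(cum), best_val)
        dropped = runmax - cum > xdrop
        if dropped.any():
            stop = int(np.argmax(dropped))
            seg = cum[: stop + 1]
            k = int(np.argmax(seg))
            if seg[k] > best_val:
                best_val = int(seg[k])
                best_len = off + k + 1
            return best_len
        k = int(np.argmax(cum))
        if cum[k] > best_val:
            best_val = int(cum[k])
            best_len = off + k + 1
        score = int(cum[-1])
        off = end
    return best_len


def _first_exact_run(
    qc: np.ndarray,
    sc: np.ndarray,
    qbad: np.ndarray,
    sbad: np.ndarray,
    q0: int,
    s0: int,
    scan: int,
    min_len: int,
) -> tuple[int, int] | None:
    """First exact-match run of >= min_len within the scan window.

    Returns (offset, run_length_at_offset) or None.
    """
    n = min(scan, len(qc) - q0, len(sc) - s0)
    if n < min_len:
        return None
    m = (qc[q0 : q0 + n] == sc[s0 : s0 + n]) & ~(qbad[q0 : q0 + n] | sbad[s0 : s0 + n])
    run = 0
    for i in range(n):
        run = run + 1 if m[i] else 0
        if run == min_len:
            start = i - min_len + 1
            j = i + 1
            while j < n and m[j]:
                j += 1
            return start, j - start
    return None


def _identity_segments(
    qc: np.ndarray,
    sc: np.ndarray,
    qbad: np.ndarray,
    sbad: np.ndarray,
    q0: int,
    s0: int,
    length: int,
) -> list[tuple[int, int]]:
    """(q_pos, len) runs of exact nucleotide identity within an ungapped piece."""
    if length <= 0:
        return []
    m = (qc[q0 : q0 + length] == sc[s0 : s0 + length]) & ~(
        qbad[q0 : q0 + length] | sbad[s0 : s0 + length]
    )
    padded = np.concatenate([[False], m, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(q0 + int(s), int(e - s)) for s, e in zip(starts, ends)]


def _extend_chain(
    qc: np.ndarray,
    sc: np.ndarray,
    qbad: np.ndarray,
    sbad: np.ndarray,
    q0: int,
    s0: int,
    cfg: ScreenConfig,
) -> list[tuple[int, int, int]]:
    """Gapped extension from a seed: a chain of ungapped (q, s, len) pieces.

    The seed is first extended ungapped in both directions, then the chain
    grows at each end by trying every indel within the band and keeping the
    one whose continuation starts with the longest exact run, for as long as
    a significant (>= min_gap_segment) ungapped segment results.
    """
    # ungapped core
    right = _xdrop_extend(qc, sc, qbad, sbad, q0, s0, cfg.xdrop)
    if q0 > 0 and s0 > 0:
        left = _xdrop_extend(
            qc[q0 - 1 :: -1], sc[s0 - 1 :: -1], qbad[q0 - 1 :: -1], sbad[s0 - 1 :: -1],
            0, 0, cfg.xdrop,
        )
    else:
        left = 0
    core = (q0 - left, s0 - left, left + right)
    if core[2] <= 0:
        return []

    chain = [core]
    chain.extend(
        _grow_right(qc, sc, qbad, sbad, core[0] + core[2], core[1] + core[2], cfg)
    )

    # grow left by mirroring: reverse both sequences and grow right
    nq, ns = len(qc), len(sc)
    rev_pieces = _grow_right(
        qc[::-1], sc[::-1], qbad[::-1], sbad[::-1], nq - core[0], ns - core[1], cfg
    )
    for qa_r, sa_r, ln in rev_pieces:
        chain.insert(0, (nq - qa_r - ln, ns - sa_r - ln, ln))
    chain.sort(key=lambda p: p[0])
    return chain


def _grow_right(qc, sc, qbad, sbad, qe, se, cfg: ScreenConfig):
    """Repeated banded indel search + ungapped extension rightwards."""
    pieces = []
    while True:
        best = None
        for delta in range(-cfg.gap_band, cfg.gap_band + 1):
            if delta == 0:
                continue
            qa, sa = (qe + delta, se) if delta > 0 else (qe, se - delta)
            if qa >= len(qc) or sa >= len(sc) or qa < 0 or sa < 0:
                continue
            hit = _first_exact_run(qc, sc, qbad, sbad, qa, sa, cfg.gap_scan, cfg.min_gap_segment)
            if hit is not None:
                off, run = hit
                cand = (run, -abs(delta), qa + off, sa + off)
                if best is None or cand > best:
                    best = cand
        if best is None:
            return pieces
        _, _, qa, sa = best
        ext = _xdrop_extend(qc, sc, qbad, sbad, qa, sa, cfg.xdrop)
        if ext < cfg.min_gap_segment:
            return pieces
        pieces.append((qa, sa, ext))
        qe, se = qa + ext, sa + ext


@dataclass
class _QueryIndex:
    keys: np.ndarray  # sorted
    starts: np.ndarray
    orient: np.ndarray

    @classmethod
    def build(cls, codes: np.ndarray, seed_mask: np.ndarray | None, cfg: ScreenConfig):
        starts, keys, orient = hmer_positions(codes, 1, QUERY_HMER)
        if seed_mask is not None and cfg.mask_seeds and len(starts):
            mid = starts + QUERY_HMER.window // 2
            ok = ~seed_mask[np.minimum(mid, len(seed_mask) - 1)]
            starts, keys, orient = starts[ok], keys[ok], orient[ok]
        order = np.argsort(keys, kind="stable")
        return cls(keys=keys[order], starts=starts[order], orient=orient[order])


def run_pass2(
    seq_id: str,
    contig_codes: np.ndarray,
    contig_filled: np.ndarray,
    chunk_spans: list[tuple[int, int]],
    db: GxDatabase,
    selected_taxa: set[int],
    runs: list[Pass1Run],
    cfg: ScreenConfig,
    seed_mask: np.ndarray | None = None,
) -> list[AlignmentHit]:
    """Refine pass-1 loci into gapped alignments using a 20-bit query index.

    Each chunk is indexed on the fly; subject neighbourhoods (bounded by
    ``min(100 kbp, 2 x chunk length)``) around the pass-1 runs of each
    selected taxon are scanned against the index, and the resulting seeds
    are extended.  Chunk hits are then merged back to contig coordinates as
    if the contig had been aligned whole.
    """
    if not selected_taxa or not runs:
        return []

    hits: list[AlignmentHit] = []
    taxon_runs: dict[int, list[Pass1Run]] = {}
    for r in runs:
        if r.taxid in selected_taxa:
            taxon_runs.setdefault(r.taxid, []).append(r)

    rc_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for c_start, c_end in chunk_spans:
        qc = contig_codes[c_start:c_end]
        qbad = contig_filled[c_start:c_end]
        qmask = seed_mask[c_start:c_end] if seed_mask is not None else None
        qindex = _QueryIndex.build(qc, qmask, cfg)
        if len(qindex.keys) == 0:
            continue
        w2 = min(cfg.neighborhood_cap, 2 * (c_end - c_start)) // 2

        for taxid, trs in sorted(taxon_runs.items()):
            by_subject: dict[int, list[Pass1Run]] = {}
            for r in trs:
                # only runs whose query locus touches this chunk
                if r.q_end > c_start and r.q_start < c_end:
                    by_subject.setdefault(r.subject_ordinal, []).append(r)
            for ordinal, srs in sorted(by_subject.items()):
                subj = db.sequences[ordinal]
                neighborhoods = _merge_windows(
                    [(r.s_start - w2, r.s_end + w2) for r in srs], subj.length
                )
                for a, b in neighborhoods:
                    hits.extend(
                        _align_neighborhood(
                            seq_id, qc, qbad, c_start, subj, a, b, ordinal,
                            taxid, qindex, rc_cache, cfg,
                        )
                    )

    return _merge_chunk_hits(hits, cfg)


def _merge_windows(windows: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    clipped = [(max(0, s), min(length, e)) for s, e in windows]
    return [iv for iv in _merge_sorted(clipped) if iv[1] > iv[0]]


def _merge_sorted(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _align_neighborhood(
    seq_id: str,
    qc: np.ndarray,
    qbad: np.ndarray,
    chunk_offset: int,
    subj,
    nb_start: int,
    nb_end: int,
    ordinal: int,
    taxid: int,
    qindex: _QueryIndex,
    rc_cache: dict,
    cfg: ScreenConfig,
) -> list[AlignmentHit]:
    w = QUERY_HMER.window
    sc_full = subj.codes
    sl = nb_end - nb_start
    if sl < w:
        return []
    s_starts, s_keys, s_orient = hmer_positions(sc_full[nb_start:nb_end], 1, QUERY_HMER)
    lo = np.searchsorted(qindex.keys, s_keys, side="left")
    hi = np.searchsorted(qindex.keys, s_keys, side="right")
    idx, owner = _expand_spans(lo, hi)
    if len(idx) == 0:
        return []

    qs = qindex.starts[idx]
    rel = (qindex.orient[idx].astype(np.int64)) * (s_orient[owner].astype(np.int64))
    ss = s_starts[owner] + nb_start  # absolute subject start of the window

    L = subj.length
    # frame coordinates: forward frame for rel=+1, reverse-complement frame
    # for rel=-1 (so extension always walks left-to-right)
    sf = np.where(rel > 0, ss, L - w - ss)
    diag = qs - sf

    order = np.lexsort((qs, diag, rel))
    qs, sf, rel, diag = qs[order], sf[order], rel[order], diag[order]

    # chain same-diagonal seeds into groups; groups of >= 2 seeds anchor
    new_group = np.ones(len(qs), dtype=bool)
    if len(qs) > 1:
        same = (rel[1:] == rel[:-1]) & (diag[1:] == diag[:-1])
        close = (qs[1:] - qs[:-1]) <= cfg.seed_group_gap
        new_group[1:] = ~(same & close)
    group_id = np.cumsum(new_group) - 1
    sizes = np.bincount(group_id)
    first = np.nonzero(new_group)[0]

    anchors = [
        (int(qs[f]), int(sf[f]), int(rel[f]), int(sizes[g]))
        for g, f in enumerate(first)
        if sizes[g] >= cfg.min_seeds_per_group
    ]
    anchors.sort(key=lambda t: (-t[3], t[0]))
    anchors = anchors[: cfg.max_anchors]
    anchors.sort(key=lambda t: (t[2], t[0] - t[1], t[0]))

    if ordinal not in rc_cache:
        rc_cache[ordinal] = (
            (3 - sc_full[::-1]).astype(np.uint8),
            subj.filled[::-1].copy(),
        )
    sc_rc, sbad_rc = rc_cache[ordinal]
    sbad_f = subj.filled

    accepted: list[tuple[int, int, int, int]] = []  # (q_lo, q_hi, d_lo, d_hi) frame coords
    out: list[AlignmentHit] = []

    for q0, s0, o, _size in anchors:
        d0 = q0 - s0
        covered = False
        for (q_lo, q_hi, d_lo, d_hi) in accepted:
            if q_lo <= q0 < q_hi and d_lo - cfg.gap_band <= d0 <= d_hi + cfg.gap_band:
                covered = True
                break
        if covered:
            continue
        sc, sbad = (sc_full, sbad_f) if o > 0 else (sc_rc, sbad_rc)
        chain = _extend_chain(qc, sc, qbad, sbad, q0, s0, cfg)
        if not chain:
            continue
        q_lo = chain[0][0]
        q_hi = chain[-1][0] + chain[-1][2]
        if q_hi - q_lo < cfg.min_hit_span:
            continue
        f_lo = chain[0][1]
        f_hi = chain[-1][1] + chain[-1][2]
        segments: list[tuple[int, int]] = []
        for qa, sa, ln in chain:
            segments.extend(_identity_segments(qc, sc, qbad, sbad, qa, sa, ln))
        if not segments or max(l for _, l in segments) < cfg.min_hit_segment:
            continue
        if o > 0:
            s_lo, s_hi = f_lo, f_hi
        else:
            s_lo, s_hi = L - f_hi, L - f_lo
        diags = [qa - sa for qa, sa, _ in chain]
        accepted.append((q_lo, q_hi, min(diags), max(diags)))
        out.append(
            AlignmentHit(
                seq_id=seq_id,
                q_start=q_lo + chunk_offset,
                q_end=q_hi + chunk_offset,
                subject_ordinal=ordinal,
                s_start=s_lo,
                s_end=s_hi,
                orientation=o,
                segments=[(q + chunk_offset, ln) for q, ln in segments],
                taxid=taxid,
            )
        )
    return out


def _merge_chunk_hits(hits: list[AlignmentHit], cfg: ScreenConfig) -> list[AlignmentHit]:
    """Deduplicate and merge hits recovered from overlapping chunks.

    Hits from the same subject and orientation whose query ranges overlap or
    abut on compatible diagonals are combined; segments falling inside the
    already-covered range are dropped so overlap bases are not double
    counted.
    """
    merged: list[AlignmentHit] = []
    hits = sorted(
        hits,
        key=lambda h: (h.taxid, h.subject_ordinal, h.orientation, h.q_start, h.q_end),
    )
    for h in hits:
        target = None
        for m in reversed(merged):
            if (
                m.taxid == h.taxid
                and m.subject_ordinal == h.subject_ordinal
                and m.orientation == h.orientation
                and h.q_start <= m.q_end
                and abs((h.q_start - h.s_start) - (m.q_start - m.s_start)) <= cfg.gap_band
            ):
                target = m
                break
            if m.taxid != h.taxid or m.q_end < h.q_start - 1:
                break
        if target is None:
            merged.append(h)
            continue
        keep = [(q, ln) for q, ln in h.segments if q >= target.q_end]
        target.segments.extend(keep)
        target.q_end = max(target.q_end, h.q_end)
        target.s_start = min(target.s_start, h.s_start)
        target.s_end = max(target.s_end, h.s_end)
    return merged


def align_contig(
    seq_id: str,
    codes: np.ndarray,
    filled: np.ndarray,
    chunk_spans: list[tuple[int, int]],
    db: GxDatabase,
    cfg: ScreenConfig,
    seed_mask_intervals: list[Interval] | None = None,
    exclude_taxids: frozenset[int] = frozenset(),
) -> tuple[list[AlignmentHit], dict[int, Pass1TaxonStats]]:
    """Run both alignment passes over one contig.

    Pass-1 statistics are accumulated across the contig's chunks before
    taxa are selected, so a taxon strong in any chunk is refined everywhere.
    """
    seed_mask = (
        _mask_bool(seed_mask_intervals, len(codes)) if seed_mask_intervals else None
    )

    all_runs: list[Pass1Run] = []
    stats: dict[int, Pass1TaxonStats] = {}
    for c_start, c_end in chunk_spans:
        mask_slice = seed_mask[c_start:c_end] if seed_mask is not None else None
        runs, chunk_stats = run_pass1(
            codes[c_start:c_end], c_start, db, cfg, mask_slice, exclude_taxids
        )
        all_runs.extend(runs)
        for taxid, st in chunk_stats.items():
            agg = stats.setdefault(taxid, Pass1TaxonStats())
            agg.n_ungapped += st.n_ungapped
            agg.max_len = max(agg.max_len, st.max_len)
            agg.sum_len += st.sum_len
            agg.sum_sq_len += st.sum_sq_len

    selected = select_taxa(stats, cfg.top_taxa_per_metric)
    hits = run_pass2(
        seq_id, codes, filled, chunk_spans, db, selected, all_runs, cfg, seed_mask
    )
    for h in hits:
        lin = db.taxonomy.resolve(h.taxid)
        h.species, h.division, h.kingdom = lin.species, lin.division, lin.kingdom
    return hits, stats
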