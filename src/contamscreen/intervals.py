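"""Half-open integer interval arithmetic used throughout the screen.

Intervals are ``(start, end)`` tuples with ``start < end``, 0-based and
half-open.  All functions return sorted, non-overlapping lists.
"""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval], gap: int = 0) -> list[Interval]:
    """Sort and merge intervals, joining neighbours separated by <= ``gap``."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1] + gap:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_length(a: list[Interval], b: list[Interval]) -> int:
    return sum(e - s for s, e in intersect(a, b))


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Portions of ``a`` not covered by ``b``."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            if b[k][0] > cur:
                out.append((cur, b[k][0]))
            cur = max(cur, b[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def clip(intervals: list[Interval], lo: int, hi: int) -> list[Interval]:
    return [(max(s, lo), min(e, hi)) for s, e in intervals if min(e, hi) > max(s, lo)]


def covered_by_at_least(tracks: list[list[Interval]], k: int) -> list[Interval]:
    """Positions covered by at least ``k`` of the given interval tracks.

    Each track contributes depth at most 1 per position (track-internal
    overlaps are merged first).
    """
    events: list[tuple[int, int]] = []
    for track in tracks:
        for s, e in merge(track):
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    out: list[Interval] = []
    depth = 0
    start = None
    for pos, delta in events:
        prev = depth
        depth += delta
        if prev < k <= depth:
            start = pos
        elif prev >= k > depth and start is not None:
            if pos > start:
                out.append((start, pos))
            start = None
    return merge(out)
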