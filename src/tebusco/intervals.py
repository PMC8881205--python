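"""Sorted-interval arithmetic: union, subtraction, priority assignment.

All functions operate on plain (start, end) half-open tuples grouped per
contig by the caller.  The implementations are event sweeps over interval
boundaries, never per-base masks, so they stay O(n log n) in the number of
intervals regardless of coordinate span.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals as a sorted, disjoint, non-adjacent list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def subtract_intervals(
    minuend: Sequence[Interval], subtrahend: Sequence[Interval]
) -> List[Interval]:
    """Per-base set difference minuend \\ subtrahend (both auto-unioned)."""
    a = merge_intervals(minuend)
    b = merge_intervals(subtrahend)
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(
    a: Sequence[Interval], b: Sequence[Interval]
) -> List[Interval]:
    """Per-base intersection of two interval sets (auto-unioned)."""
    ua, ub = merge_intervals(a), merge_intervals(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(ua) and j < len(ub):
        s = max(ua[i][0], ub[j][0])
        e = min(ua[i][1], ub[j][1])
        if s < e:
            out.append((s, e))
        if ua[i][1] < ub[j][1]:
            i += 1
        else:
            j += 1
    return out


def assign_by_priority(
    segments: Sequence[Interval],
    annotations: Sequence[Tuple[Interval, object]],
    priority: Callable[[object], tuple],
) -> Dict[object, int]:
    """Assign every base of ``segments`` to the highest-priority overlapping
    annotation payload; unassigned bases are returned under ``None``.

    ``priority(payload)`` returns a sort key; the LARGEST key wins a base.
    Event sweep over boundary points: within an elementary segment the set
    of active annotations is constant, so one winner covers it.
    """
    segs = merge_intervals(segments)
    if not segs:
        return {}
    events: List[Tuple[int, int, int]] = []  # (pos, kind, ann_index)
    # kind 0 = annotation start, 1 = annotation end
    anns = list(annotations)
    for idx, ((s, e), _payload) in enumerate(anns):
        if e > s:
            events.append((s, 0, idx))
            events.append((e, 1, idx))
    boundaries = sorted(
        {p for p, _, _ in events}
        | {s for s, _ in segs}
        | {e for _, e in segs}
    )
    events.sort()
    counts: Dict[object, int] = {}
    active: Dict[int, tuple] = {}  # ann index -> priority key
    ei = 0
    si = 0
    for bi in range(len(boundaries) - 1):
        lo, hi = boundaries[bi], boundaries[bi + 1]
        while ei < len(events) and events[ei][0] <= lo:
            _, kind, idx = events[ei]
            if kind == 0:
                active[idx] = priority(anns[idx][1])
            else:
                active.pop(idx, None)
            ei += 1
        # overlap of [lo, hi) with the segment union
        while si < len(segs) and segs[si][1] <= lo:
            si += 1
        if si >= len(segs):
            break
        span = min(hi, segs[si][1]) - max(lo, segs[si][0])
        if span <= 0:
            continue
        if active:
            winner = max(active, key=active.get)
            payload = anns[winner][1]
        else:
            payload = None
        counts[payload] = counts.get(payload, 0) + span
    return counts
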