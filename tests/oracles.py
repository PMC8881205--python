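"""Independent oracles used by the test suite.

Everything here deliberately takes the slow, obviously-correct route
(per-base boolean masks, brute-force enumeration, dynamic programming via
biopython) so it shares no code path with the package's sorted-interval
sweeps and seeded search.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import Align

Interval = Tuple[int, int]


def bitmask_union(intervals: Sequence[Interval], span: int) -> np.ndarray:
    mask = np.zeros(span, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def bitmask_subtract(
    a: Sequence[Interval], b: Sequence[Interval], span: int
) -> np.ndarray:
    return bitmask_union(a, span) & ~bitmask_union(b, span)


def mask_to_intervals(mask: np.ndarray) -> List[Interval]:
    out: List[Interval] = []
    in_run = False
    for i, v in enumerate(mask):
        if v and not in_run:
            start, in_run = i, True
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def bitmask_priority_assignment(
    segments: Sequence[Interval],
    annotations: Sequence[Tuple[Interval, object, tuple]],
    span: int,
) -> Dict[object, int]:
    """Per-base winner-takes-base assignment; annotations carry explicit
    priority keys (largest wins).  Returns payload -> base count with
    ``None`` for uncovered segment bases."""
    seg_mask = bitmask_union(segments, span)
    winner = np.full(span, -1, dtype=int)
    order = sorted(range(len(annotations)),
                   key=lambda i: annotations[i][2])
    for idx in order:  # ascending priority: later (higher) overwrites
        (s, e), _, _ = annotations[idx]
        winner[s:e] = idx
    counts: Dict[object, int] = {}
    for pos in np.nonzero(seg_mask)[0]:
        w = winner[pos]
        payload = annotations[w][1] if w >= 0 else None
        counts[payload] = counts.get(payload, 0) + 1
    return counts


def local_alignment_score(query: str, subject: str,
                          match: float = 1.0, mismatch: float = -2.0,
                          gap_open: float = 5.0,
                          gap_extend: float = 1.0) -> float:
    """Smith-Waterman local alignment score via biopython."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(query.upper(), subject.upper()))


def brute_force_canonical_kmers(seq: str, k: int) -> Dict[str, int]:
    comp = str.maketrans("ACGT", "TGCA")
    counts: Dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k].upper()
        if set(kmer) - set("ACGT"):
            continue
        rc = kmer.translate(comp)[::-1]
        canon = min(kmer, rc)
        counts[canon] = counts.get(canon, 0) + 1
    return counts


def exhaustive_region_scan(
    raw: np.ndarray, baseline: float, fold: float, min_len: int,
    window: int,
) -> List[Interval]:
    """Per-position threshold scan + run merging, mirroring the detector's
    contract by brute force (moving mean computed position by position)."""
    n = raw.size
    half = window // 2
    smoothed = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + (window - half))
        # replicate 'nearest' edge handling: pad with edge values
        vals = []
        for j in range(i - half, i + (window - half)):
            vals.append(raw[min(max(j, 0), n - 1)])
        smoothed[i] = np.mean(vals)
    mask = smoothed >= fold * baseline
    runs = mask_to_intervals(mask)
    merged: List[Interval] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < window:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_len]
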