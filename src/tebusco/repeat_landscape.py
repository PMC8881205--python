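"""Repeat-annotation summaries: category mapping, two-pass merging,
genome-proportion accounting and divergence-binned age landscapes.

Repeat ages are read from the divergence column of the annotation (percent
divergence of each genomic copy from its family consensus).  A family whose
copies concentrate at low divergence (roughly 0-10%) has a recent history of
activity; mass at higher divergence reflects older proliferation.  Landscapes
here are assembly-annotation based: abundance is annotated bases in the
assembly, not read-cluster abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ConsistencyError, GenomicInterval, RepeatHit
from .intervals import assign_by_priority, merge_intervals, subtract_intervals

logger = logging.getLogger(__name__)

#: Canonical reporting categories.  "Other" pools rolling circles, Penelope,
#: low-complexity and simple repeats, and small RNAs.
CATEGORIES = ("SINE", "LINE", "LTR", "DNA", "Satellite", "Other", "Unclassified")

_OTHER_PREFIXES = ("RC", "PENELOPE", "LOW_COMPLEXITY", "SIMPLE_REPEAT",
                   "SMRNA", "SNRNA", "TRNA", "RRNA", "SCRNA", "SRNA")


def map_category(raw_class: str) -> str:
    """Map a raw class/family string (e.g. ``LINE/L2``) to its canonical
    reporting category; unrecognized strings map to ``Unclassified``."""
    head = raw_class.split("/", 1)[0].strip()
    up = head.upper()
    if up == "SINE":
        return "SINE"
    if up == "LINE":
        return "LINE"
    if up == "LTR":
        return "LTR"
    if up == "DNA":
        return "DNA"
    if up == "SATELLITE":
        return "Satellite"
    if up in _OTHER_PREFIXES:
        return "Other"
    if up in ("UNKNOWN", "UNCLASSIFIED", ""):
        return "Unclassified"
    logger.warning("unrecognized repeat class %r mapped to Unclassified", raw_class)
    return "Unclassified"


@dataclass
class RepeatSummary:
    """Disjoint per-category base counts and genome proportions."""

    genome_length: int
    bases: Dict[str, int]
    masked_bases: int

    @property
    def proportions(self) -> Dict[str, float]:
        return {c: b / self.genome_length for c, b in self.bases.items()}

    @property
    def masked_proportion(self) -> float:
        return self.masked_bases / self.genome_length


@dataclass
class LandscapeBins:
    """category x divergence-bin matrix of genome proportions."""

    bin_width: float
    categories: List[str]
    bin_starts: np.ndarray
    matrix: np.ndarray  # shape (n_categories, n_bins), genome proportions

    def category_row(self, category: str) -> np.ndarray:
        return self.matrix[self.categories.index(category)]

    @property
    def total_proportion(self) -> float:
        return float(self.matrix.sum())


def _hit_priority(hit: RepeatHit) -> tuple:
    # higher score wins; ties: earlier interval, then lexicographically
    # earlier family (negated ordinals so that max() picks it)
    return (
        hit.score,
        -hit.interval.start,
        -hit.interval.end,
        tuple(-ord(c) for c in hit.family),
    )


def _group_by_contig(hits: Sequence[RepeatHit]) -> Dict[str, List[RepeatHit]]:
    out: Dict[str, List[RepeatHit]] = {}
    for h in hits:
        out.setdefault(h.interval.contig, []).append(h)
    return out


def merge_repeat_runs(
    run1: Sequence[RepeatHit], run2: Sequence[RepeatHit]
) -> List[RepeatHit]:
    """Merge two annotation passes with first-pass priority.

    The second pass is normally run on a hardmasked assembly and should be
    disjoint from the first; where it is not, the overlapping portion of a
    second-pass hit is trimmed away so every base keeps its first-pass
    assignment.  Trimming can split a second-pass hit in two.
    """
    by1 = _group_by_contig(run1)
    merged: List[RepeatHit] = list(run1)
    for hit in run2:
        mask = merge_intervals(
            (h.interval.start, h.interval.end)
            for h in by1.get(hit.interval.contig, [])
        )
        pieces = subtract_intervals(
            [(hit.interval.start, hit.interval.end)], mask
        )
        for s, e in pieces:
            merged.append(
                RepeatHit(
                    interval=GenomicInterval(
                        hit.interval.contig, s, e, hit.interval.strand
                    ),
                    family=hit.family,
                    raw_class=hit.raw_class,
                    category=hit.category,
                    divergence=hit.divergence,
                    score=hit.score,
                )
            )
    merged.sort(key=lambda h: (h.interval.contig, h.interval.start, h.interval.end))
    return merged


def _per_hit_base_assignment(
    hits: Sequence[RepeatHit],
) -> Dict[RepeatHit, int]:
    """Disjoint per-base assignment of annotated bases to hits.

    Overlapping annotations are resolved by score (then earlier start, then
    family name) so summed bases never double-count a genome position.
    """
    assigned: Dict[RepeatHit, int] = {}
    for contig, contig_hits in _group_by_contig(hits).items():
        anns = [
            ((h.interval.start, h.interval.end), h) for h in contig_hits
        ]
        segments = [(h.interval.start, h.interval.end) for h in contig_hits]
        counts = assign_by_priority(segments, anns, _hit_priority)
        for payload, n in counts.items():
            if payload is None:
                continue
            assigned[payload] = assigned.get(payload, 0) + n
    return assigned


def summarize_repeats(
    hits: Sequence[RepeatHit], genome_length: int
) -> RepeatSummary:
    """Per-category base counts / genome proportions (disjoint per base)."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    assigned = _per_hit_base_assignment(hits)
    bases = {c: 0 for c in CATEGORIES}
    for hit, n in assigned.items():
        bases[hit.category] = bases.get(hit.category, 0) + n
    masked = sum(
        sum(e - s for s, e in merge_intervals(
            (h.interval.start, h.interval.end) for h in contig_hits
        ))
        for contig_hits in _group_by_contig(hits).values()
    )
    return RepeatSummary(genome_length=genome_length, bases=bases,
                         masked_bases=masked)


def divergence_landscape(
    hits: Sequence[RepeatHit],
    genome_length: int,
    bin_width: float = 1.0,
    kimura_correction: bool = False,
) -> LandscapeBins:
    """Bin disjointly-assigned repeat bases by percent divergence.

    Divergence beyond 50% is pooled into the last bin.  With
    ``kimura_correction`` the raw proportion p of mismatching sites is
    replaced by the Jukes/Kimura-style distance -0.75*ln(1 - 4p/3) x 100
    before binning (off by default; raw percent is what the annotation
    carries).
    """
    if bin_width not in (1, 2, 5):
        raise ValueError("bin_width must be one of 1, 2, 5")
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    n_bins = int(np.ceil(50 / bin_width))
    matrix = np.zeros((len(CATEGORIES), n_bins), dtype=float)
    assigned = _per_hit_base_assignment(hits)
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    for hit, n in assigned.items():
        div = hit.divergence
        if kimura_correction:
            p = min(div / 100.0, 0.74)
            div = -0.75 * np.log(1.0 - 4.0 * p / 3.0) * 100.0
        b = min(int(div // bin_width), n_bins - 1)
        matrix[cat_index[hit.category], b] += n / genome_length
    return LandscapeBins(
        bin_width=float(bin_width),
        categories=list(CATEGORIES),
        bin_starts=np.arange(n_bins) * float(bin_width),
        matrix=matrix,
    )
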