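"""Detection of TE-associated single-copy orthologs from coverage profiles.

A BUSCO gene whose span contains repeat-derived sequence shows anomalously
high read-mapping depth over that fragment: reads from every genomic copy
of the repeat family pile up on it.  The detector smooths the depth profile
over each gene span, finds maximal runs at or above a fold threshold of a
robust baseline, and flags genes carrying at least one sufficiently long
run ("TE-associated BUSCOs").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import (
    BaselineError,
    BuscoRecord,
    CoverageTrack,
    GenomicInterval,
    ParameterError,
)


@dataclass(frozen=True)
class ProfileParams:
    """Detection thresholds.

    fold_threshold
        multiple of the baseline a (smoothed) position must reach.
    min_region_length
        minimum run length in bp for a reportable region.
    smoothing_window
        moving-mean window (bp) applied to the profile before
        thresholding; regions closer than this are merged.
    baseline_mode
        ``busco_median`` pools per-base depth over all Complete gene spans;
        ``genome_median`` uses all positions with depth > 0.
    min_baseline
        depth floor below which a low-coverage warning is raised.
    """

    fold_threshold: float = 2.0
    min_region_length: int = 50
    smoothing_window: int = 25
    baseline_mode: str = "busco_median"
    min_baseline: float = 5.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1.0:
            raise ParameterError("fold_threshold must exceed 1")
        if self.min_region_length < 1 or self.smoothing_window < 1:
            raise ParameterError("lengths/windows must be >= 1")
        if self.baseline_mode not in ("busco_median", "genome_median"):
            raise ParameterError(
                f"unknown baseline_mode {self.baseline_mode!r}"
            )


@dataclass(frozen=True)
class HighCoverageRegion:
    busco_id: str
    interval: GenomicInterval
    mean_fold: float
    baseline: float


@dataclass
class BuscoFlag:
    busco_id: str
    te_associated: bool
    regions: List[HighCoverageRegion]


@dataclass
class TEAssociationReport:
    """Per-gene flags plus the headline fraction of TE-associated BUSCOs."""

    flags: Dict[str, BuscoFlag]
    baseline: float
    params: ProfileParams
    denominator_mode: str
    n_te_associated: int
    n_denominator: int

    @property
    def fraction(self) -> float:
        return self.n_te_associated / self.n_denominator

    def flagged_ids(self) -> List[str]:
        return [b for b, f in self.flags.items() if f.te_associated]

    def regions_of(self, busco_id: str) -> List[HighCoverageRegion]:
        return self.flags[busco_id].regions


class LowCoverageWarning(UserWarning):
    pass


def coverage_baseline(
    track: CoverageTrack,
    buscos: Sequence[BuscoRecord],
    params: ProfileParams = ProfileParams(),
) -> float:
    """Baseline ("expected") depth against which inflation is measured."""
    if params.baseline_mode == "busco_median":
        spans = [
            track.slice(b.interval)
            for b in buscos
            if b.status == "Complete" and b.interval is not None
        ]
        if not spans:
            raise BaselineError("no Complete BUSCO spans for the baseline")
        pooled = np.concatenate(spans)
    else:
        pooled = track.all_positions()
        pooled = pooled[pooled > 0]
    if pooled.size == 0:
        raise BaselineError("no usable positions for the baseline")
    baseline = float(np.median(pooled))
    if baseline < params.min_baseline:
        warnings.warn(
            f"baseline depth {baseline:.1f} below floor "
            f"{params.min_baseline:g}; detection may be unreliable",
            LowCoverageWarning,
        )
    return baseline


def _runs_above(mask: np.ndarray) -> List[tuple]:
    """Maximal runs of True as (start, end) offsets."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def detect_high_coverage_regions(
    record: BuscoRecord,
    track: CoverageTrack,
    baseline: float,
    params: ProfileParams = ProfileParams(),
) -> List[HighCoverageRegion]:
    """High-coverage runs inside one gene span.

    The depth profile over the span is smoothed with a moving mean, then
    maximal runs with smoothed depth >= fold_threshold x baseline and
    length >= min_region_length are reported; runs separated by less than
    the smoothing window are merged first.  ``mean_fold`` is computed on
    the raw (unsmoothed) profile.
    """
    if record.interval is None:
        raise ParameterError(f"BUSCO {record.busco_id} has no interval")
    if baseline <= 0:
        raise ParameterError("baseline must be positive")
    raw = track.slice(record.interval).astype(float)
    smoothed = uniform_filter1d(raw, size=params.smoothing_window,
                                mode="nearest")
    mask = smoothed >= params.fold_threshold * baseline
    runs = _runs_above(mask)
    # merge runs separated by less than the smoothing window
    merged: List[tuple] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < params.smoothing_window:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    regions = []
    for s, e in merged:
        if e - s < params.min_region_length:
            continue
        iv = GenomicInterval(
            record.interval.contig,
            record.interval.start + s,
            record.interval.start + e,
            record.interval.strand,
        )
        regions.append(
            HighCoverageRegion(
                busco_id=record.busco_id,
                interval=iv,
                mean_fold=float(raw[s:e].mean() / baseline),
                baseline=baseline,
            )
        )
    return regions


def classify_te_associated(
    buscos: Sequence[BuscoRecord],
    track: CoverageTrack,
    params: ProfileParams = ProfileParams(),
    denominator_mode: str = "complete_only",
) -> TEAssociationReport:
    """Flag TE-associated BUSCOs and report their overall fraction.

    A gene is flagged iff it has at least one high-coverage region.
    Duplicated-status genes are profiled per copy but counted once per id.
    The denominator is the number of distinct Complete ids
    (``complete_only``) or Complete plus Duplicated ids
    (``complete_plus_duplicated``).
    """
    if denominator_mode not in ("complete_only", "complete_plus_duplicated"):
        raise ParameterError(f"unknown denominator_mode {denominator_mode!r}")
    baseline = coverage_baseline(track, buscos, params)
    statuses = ("Complete",) if denominator_mode == "complete_only" else (
        "Complete", "Duplicated")
    flags: Dict[str, BuscoFlag] = {}
    for rec in buscos:
        if rec.status not in statuses or rec.interval is None:
            continue
        regions = detect_high_coverage_regions(rec, track, baseline, params)
        flag = flags.setdefault(
            rec.busco_id, BuscoFlag(rec.busco_id, False, [])
        )
        flag.regions.extend(regions)
        if regions:
            flag.te_associated = True
    n_flagged = sum(1 for f in flags.values() if f.te_associated)
    if not flags:
        raise BaselineError("no BUSCOs eligible for classification")
    return TEAssociationReport(
        flags=flags,
        baseline=baseline,
        params=params,
        denominator_mode=denominator_mode,
        n_te_associated=n_flagged,
        n_denominator=len(flags),
    )
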