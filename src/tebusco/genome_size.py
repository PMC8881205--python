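"""Coverage-peak genome-size estimation and method-agreement statistics.

The back-mapping estimator divides the total number of mapped bases by the
modal (1C) per-base depth of the coverage distribution: if reads from the
whole genome map onto an assembly at haploid depth c, total mapped bases
are c x G and the histogram peaks at c, recovering G even when repeats are
collapsed in the assembly (their reads still count, piling up at inflated
depth).  A naive k-mer multiplicity-peak estimator is provided as a
deliberately simple comparator — it is not a fit of the full genome-profiling
mixture model.  Agreement between paired estimates from two methods is
summarized with Bland-Altman bias and 95% limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import CoverageTrack, EstimationError

MB = 1_000_000


@dataclass
class DepthHistogram:
    """Counts of positions (or distinct k-mers) per integer depth."""

    counts: np.ndarray  # index = depth (or multiplicity), value = count
    total_mapped_bases: int
    min_depth: int = 1

    @property
    def max_depth(self) -> int:
        return self.counts.size - 1

    def mean_depth(self) -> float:
        depths = np.arange(self.counts.size)
        mass = self.counts[self.min_depth :].sum()
        if mass == 0:
            raise EstimationError("no positions at or above min_depth")
        return float(
            (depths[self.min_depth :] * self.counts[self.min_depth :]).sum()
            / mass
        )


@dataclass(frozen=True)
class GenomeSizeEstimate:
    method: str  # backmap_peak | kmer_peak | external
    size_bp: float
    peak_depth: Optional[int]
    total_bases_or_kmers: int

    @property
    def size_mb(self) -> float:
        return self.size_bp / MB


@dataclass
class MethodComparison:
    """Bland-Altman agreement between two paired size-estimate vectors."""

    differences: np.ndarray  # a - b per species
    means: np.ndarray        # (a + b) / 2 per species
    bias: float
    loa_low: float
    loa_high: float
    n: int


class AmbiguousPeakWarning(UserWarning):
    pass


def depth_histogram(
    track: CoverageTrack, min_depth: int = 1
) -> DepthHistogram:
    """Histogram of per-base depths over a coverage track.

    Positions below ``min_depth`` are excluded from peak finding but their
    bases still count toward ``total_mapped_bases``.
    """
    pooled = track.all_positions()
    counts = np.bincount(pooled) if pooled.size else np.zeros(1, dtype=np.int64)
    return DepthHistogram(
        counts=counts.astype(np.int64),
        total_mapped_bases=track.total_mapped_bases,
        min_depth=min_depth,
    )


def _smoothed(counts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or counts.size <= 1:
        return counts.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(counts.astype(float), kernel, mode="same")


def estimate_size_backmap(
    hist: DepthHistogram, smooth: int = 3
) -> GenomeSizeEstimate:
    """Genome size = total mapped bases / modal (1C) depth.

    The histogram is smoothed with a moving average (window ``smooth``)
    before the argmax search over depths >= ``min_depth``.  On ties the
    lowest-depth peak is chosen (haploid-peak convention) and an
    ambiguity warning lists the candidates.
    """
    if hist.counts[hist.min_depth :].sum() == 0:
        raise EstimationError("histogram has no positive-depth mass")
    sm = _smoothed(hist.counts, smooth)
    search = sm[hist.min_depth :]
    candidates = np.nonzero(search == search.max())[0] + hist.min_depth
    # smoothing flattens an isolated spike across its neighbours; break
    # smoothed ties by the raw count, then by the lowest depth (haploid
    # peak convention)
    raw = hist.counts[candidates]
    candidates = candidates[raw == raw.max()]
    peak = int(candidates[0])
    if candidates.size > 1:
        warnings.warn(
            f"ambiguous coverage peak; candidates {candidates.tolist()}, "
            f"choosing lowest ({peak})",
            AmbiguousPeakWarning,
        )
    return GenomeSizeEstimate(
        method="backmap_peak",
        size_bp=hist.total_mapped_bases / peak,
        peak_depth=peak,
        total_bases_or_kmers=hist.total_mapped_bases,
    )


def kmer_histogram(
    sequences: Iterable[str], k: int = 21
) -> DepthHistogram:
    """Multiplicity histogram of canonical k-mers.

    ``counts[m]`` = number of distinct canonical k-mers occurring exactly
    m times across all sequences; k-mers containing N are skipped, as are
    sequences shorter than k (with a warning).
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and within [11, 31]")
    from .core import encode_sequence, reverse_complement
    from .te_quantify import _kmer_code_array

    all_codes: List[np.ndarray] = []
    for seq in sequences:
        if len(seq) < k:
            warnings.warn(f"sequence shorter than k={k} skipped")
            continue
        codes, invalid = _kmer_code_array(encode_sequence(seq.upper()), k)
        all_codes.append(codes[~invalid])
    if not all_codes or sum(a.size for a in all_codes) == 0:
        return DepthHistogram(
            counts=np.zeros(1, dtype=np.int64), total_mapped_bases=0
        )
    pooled = np.concatenate(all_codes)
    canon = np.minimum(pooled, _revcomp_codes(pooled, k))
    _, mult = np.unique(canon, return_counts=True)
    hist = np.bincount(mult)
    hist[0] = 0
    total = int((np.arange(hist.size) * hist).sum())
    return DepthHistogram(
        counts=hist.astype(np.int64), total_mapped_bases=total
    )


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse complements of 2-bit packed k-mer codes (A=0,C=1,G=2,T=3)."""
    out = np.zeros_like(codes)
    work = codes.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (np.uint64(3) - (work & np.uint64(3)))
        work = work >> np.uint64(2)
    return out


def estimate_size_kmer_peak(
    hist: DepthHistogram, read_mode: bool = False
) -> GenomeSizeEstimate:
    """Naive k-mer peak genome-size estimate.

    In read mode, size = total k-mers / peak multiplicity (the coverage
    peak); in assembly mode every k-mer is expected once, so the estimate
    is simply the total k-mer count.  This is the simple comparator to the
    back-mapping method, not a mixture-model fit.
    """
    if hist.counts[hist.min_depth :].sum() == 0:
        raise EstimationError("k-mer histogram is empty")
    if read_mode:
        sm = _smoothed(hist.counts, 3)
        search = sm[hist.min_depth :]
        candidates = np.nonzero(search == search.max())[0] + hist.min_depth
        peak = int(candidates[0])
        if candidates.size > 1:
            warnings.warn(
                f"ambiguous k-mer peak; candidates {candidates.tolist()}",
                AmbiguousPeakWarning,
            )
        size = hist.total_mapped_bases / peak
    else:
        peak = 1
        size = float(hist.total_mapped_bases)
    return GenomeSizeEstimate(
        method="kmer_peak",
        size_bp=size,
        peak_depth=peak,
        total_bases_or_kmers=hist.total_mapped_bases,
    )


def bland_altman(
    a: Sequence[float], b: Sequence[float]
) -> MethodComparison:
    """Bland-Altman agreement of two paired measurement vectors.

    bias = mean(a - b); 95% limits of agreement = bias -/+ 1.96 x SD of
    the differences (sample SD, n-1).
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("paired vectors must have equal length")
    if av.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(av).any() or np.isnan(bv).any():
        raise ValueError("missing values are not allowed")
    diffs = av - bv
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return MethodComparison(
        differences=diffs,
        means=(av + bv) / 2.0,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=av.size,
    )


def read_external_sizes(path: str) -> Dict[str, float]:
    """Read externally measured genome sizes (species, size_Mb) TSV.

    Returns sizes in bp.
    """
    out: Dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            species, size_mb = line.split("\t")[:2]
            out[species] = float(size_mb) * MB
    return out
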