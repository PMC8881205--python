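"""Quantification of repeat content linked to TE-associated genes.

The chain mirrors the discovery workflow: use the gene's genomic sequence
as a query in a nucleotide search against its own assembly (thousands of
hits when the gene carries a multi-copy repeat fragment), filter the hits,
merge their subject intervals per base, subtract every Complete
single-copy-ortholog locus, and intersect what remains with the repeat
annotation to attribute bases to repeat categories.  A reference-species
contrast (re-running with the homologous gene that lacks the fragment) and
a pairwise-alignment validation (the reference shows an alignment gap
exactly over the high-coverage region) complete the evidence.

The built-in search backend is an exact-k-mer seeded, ungapped x-drop
extension scorer with Karlin-Altschul-style e-values from declared
constants; externally produced 12-column tabular hits are accepted as a
first-class alternative backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .core import (
    BuscoRecord,
    ConsistencyError,
    GenomeSequenceSet,
    GenomicInterval,
    ParameterError,
    RepeatHit,
    SearchHit,
    encode_sequence,
    reverse_complement,
)
from .intervals import (
    assign_by_priority,
    merge_intervals,
    subtract_intervals,
    total_length,
)
from .repeat_landscape import CATEGORIES

#: Karlin-Altschul-style scaling constants for the +1/-2 ungapped scoring
#: system.  E-values computed from them are comparative rankings, not
#: calibrated against any external search tool.
KA_LAMBDA = 1.28
KA_K = 0.46


@dataclass(frozen=True)
class SearchParams:
    backend: str = "builtin"  # builtin | external_table
    # blastn-like seed: long (megablast-style) seeds miss repeat copies
    # beyond ~10% pairwise divergence, which the pipeline must find
    seed_length: int = 15
    x_drop: float = 20.0
    match_score: float = 1.0
    mismatch_score: float = -2.0
    max_evalue: float = 1e-5
    min_alignment_length: int = 50
    min_identity: float = 80.0

    def __post_init__(self) -> None:
        if self.seed_length < 8:
            raise ParameterError("seed_length must be >= 8")
        if self.x_drop <= 0 or self.max_evalue <= 0:
            raise ParameterError("thresholds must be positive")
        if self.backend not in ("builtin", "external_table"):
            raise ParameterError(f"unknown backend {self.backend!r}")


@dataclass
class CategoryBaseCounts:
    """Per-category base attribution of residual hit intervals."""

    bases: Dict[str, int]
    unannotated_bases: int
    total_bases: int

    def dominant_category(self) -> Optional[str]:
        annotated = {c: b for c, b in self.bases.items() if b > 0}
        if not annotated:
            return None
        return max(annotated, key=lambda c: (annotated[c], c))


@dataclass(frozen=True)
class ContrastResult:
    busco_id: str
    inflated_total_bases: int
    reference_total_bases: int

    @property
    def ratio(self) -> float:
        return self.inflated_total_bases / max(self.reference_total_bases, 1)


@dataclass(frozen=True)
class ValidationVerdict:
    busco_id: str
    aligned: bool
    gap_overlaps_flagged_region: bool
    largest_unaligned_query_segment: int


# ------------------------------------------------------------ search

def _kmer_code_array(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit k-mer codes and a contains-N invalidity mask."""
    m = codes.size - k + 1
    if m <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    out = np.zeros(m, dtype=np.uint64)
    invalid = np.zeros(m, dtype=bool)
    for j in range(k):
        col = codes[j : j + m]
        out = (out << np.uint64(2)) | np.minimum(col, 3).astype(np.uint64)
        invalid |= col == 4
    return out, invalid


def _genome_kmer_codes(
    genome: GenomeSequenceSet, contig: str, k: int
) -> Tuple[np.ndarray, np.ndarray]:
    cache = getattr(genome, "_kmer_cache", None)
    if cache is None:
        cache = {}
        setattr(genome, "_kmer_cache", cache)
    key = (contig, k)
    if key not in cache:
        cache[key] = _kmer_code_array(genome.encoded(contig), k)
    return cache[key]


def _xdrop_extend_right(
    scores: np.ndarray, x_drop: float
) -> Tuple[int, float]:
    """Best prefix of a per-position score vector under x-drop termination.

    Returns (number of positions taken, score gained)."""
    if scores.size == 0:
        return 0, 0.0
    cs = np.cumsum(scores)
    runmax = np.maximum.accumulate(cs)
    dropped = np.nonzero(runmax - cs > x_drop)[0]
    limit = int(dropped[0]) if dropped.size else scores.size
    if limit == 0:
        return 0, 0.0
    best = int(np.argmax(cs[:limit]))
    if cs[best] <= 0:
        return 0, 0.0
    return best + 1, float(cs[best])


def _merge_seed_runs(qpos: np.ndarray, k: int) -> List[Tuple[int, int]]:
    """Merge sorted seed query positions on one diagonal into runs."""
    runs: List[Tuple[int, int]] = []
    for q in qpos:
        q = int(q)
        if runs and q <= runs[-1][1]:
            runs[-1] = (runs[-1][0], max(runs[-1][1], q + k))
        else:
            runs.append((q, q + k))
    return runs


def _evalue(score: float, query_len: int, genome_len: int) -> float:
    return float(KA_K * query_len * genome_len * np.exp(-KA_LAMBDA * score))


def _bit_score(score: float) -> float:
    return float((KA_LAMBDA * score - np.log(KA_K)) / np.log(2.0))


def seed_extend_search(
    query: str,
    genome: GenomeSequenceSet,
    params: SearchParams = SearchParams(),
    query_id: str = "query",
) -> List[SearchHit]:
    """Search ``query`` against ``genome`` on both strands.

    Exact k-mer seeds are grouped per diagonal, merged into runs, extended
    without gaps under x-drop termination, and overlapping same-diagonal
    extensions are collapsed.  Hits are ordered by (subject contig, subject
    start, query start).
    """
    k = params.seed_length
    if len(query) < k:
        raise ParameterError(
            f"query length {len(query)} shorter than seed length {k}"
        )
    genome_len = genome.total_length
    query = query.upper()
    hits: List[SearchHit] = []
    for strand in ("+", "-"):
        qseq = query if strand == "+" else reverse_complement(query)
        qcodes = encode_sequence(qseq)
        qk, qk_invalid = _kmer_code_array(qcodes, k)
        lookup: Dict[int, List[int]] = {}
        for pos in range(qk.size):
            if not qk_invalid[pos]:
                lookup.setdefault(int(qk[pos]), []).append(pos)
        if not lookup:
            continue
        probe = np.fromiter(lookup.keys(), dtype=np.uint64, count=len(lookup))
        for contig in genome.contigs:
            gk, gk_invalid = _genome_kmer_codes(genome, contig, k)
            if gk.size == 0:
                continue
            match_mask = np.isin(gk, probe)
            match_mask &= ~gk_invalid
            spos = np.nonzero(match_mask)[0]
            if spos.size == 0:
                continue
            # seeds as (diagonal, query position)
            diags: List[int] = []
            qposs: List[int] = []
            for sp in spos:
                for qp in lookup[int(gk[sp])]:
                    diags.append(int(sp) - qp)
                    qposs.append(qp)
            diag_arr = np.asarray(diags)
            qpos_arr = np.asarray(qposs)
            order = np.lexsort((qpos_arr, diag_arr))
            diag_arr, qpos_arr = diag_arr[order], qpos_arr[order]
            gcodes = genome.encoded(contig)
            for d in np.unique(diag_arr):
                sel = qpos_arr[diag_arr == d]
                spans = []
                for q0, q1 in _merge_seed_runs(sel, k):
                    qs, qe = _extend_run(
                        qcodes, gcodes, int(d), q0, q1, params
                    )
                    spans.append((qs, qe))
                for qs, qe in merge_intervals(spans):
                    hits.append(
                        _make_hit(
                            qcodes, gcodes, int(d), qs, qe, strand,
                            contig, len(query), genome_len, params, query_id,
                        )
                    )
    hits.sort(
        key=lambda h: (
            h.subject_interval.contig,
            h.subject_interval.start,
            h.query_start,
        )
    )
    return hits


def _extend_run(
    qcodes: np.ndarray,
    gcodes: np.ndarray,
    d: int,
    q0: int,
    q1: int,
    params: SearchParams,
) -> Tuple[int, int]:
    """Ungapped x-drop extension of a seed run on diagonal ``d``."""
    qlen, glen = qcodes.size, gcodes.size
    lo = max(0, -d)                 # smallest legal query position
    hi = min(qlen, glen - d)        # one past largest legal query position

    def scores(a: int, b: int) -> np.ndarray:
        qs = qcodes[a:b]
        ss = gcodes[a + d : b + d]
        eq = (qs == ss) & (qs != 4) & (ss != 4)
        return np.where(eq, params.match_score, params.mismatch_score)

    right_n, _ = _xdrop_extend_right(scores(q1, hi), params.x_drop)
    left_n, _ = _xdrop_extend_right(scores(lo, q0)[::-1], params.x_drop)
    return q0 - left_n, q1 + right_n


def _make_hit(
    qcodes: np.ndarray,
    gcodes: np.ndarray,
    d: int,
    qs: int,
    qe: int,
    strand: str,
    contig: str,
    orig_query_len: int,
    genome_len: int,
    params: SearchParams,
    query_id: str,
) -> SearchHit:
    qseg = qcodes[qs:qe]
    sseg = gcodes[qs + d : qe + d]
    matches = int(((qseg == sseg) & (qseg != 4) & (sseg != 4)).sum())
    length = qe - qs
    mismatches = length - matches
    score = matches * params.match_score + mismatches * params.mismatch_score
    if strand == "+":
        q_start, q_end = qs, qe
    else:  # map back from the reverse-complement frame
        q_start, q_end = orig_query_len - qe, orig_query_len - qs
    return SearchHit(
        query_id=query_id,
        query_start=q_start,
        query_end=q_end,
        subject_interval=GenomicInterval(contig, qs + d, qe + d, strand),
        percent_identity=100.0 * matches / length,
        alignment_length=length,
        e_value=_evalue(score, orig_query_len, genome_len),
        bit_score=_bit_score(score),
        mismatches=mismatches,
    )


def filter_hits(
    hits: Sequence[SearchHit], params: SearchParams = SearchParams()
) -> List[SearchHit]:
    """Keep hits passing the e-value, length and identity thresholds."""
    return [
        h
        for h in hits
        if h.e_value <= params.max_evalue
        and h.alignment_length >= params.min_alignment_length
        and h.percent_identity >= params.min_identity
    ]


# ------------------------------------------------- interval accounting

IntervalSet = Dict[str, List[Tuple[int, int]]]


def subtract_busco_loci(
    hits: Sequence[SearchHit],
    complete_busco_intervals: Sequence[GenomicInterval],
) -> Tuple[IntervalSet, int]:
    """Union hit subject intervals per contig, then subtract gene loci.

    The per-base union prevents double counting across overlapping hits;
    the subtraction removes every base inside a Complete single-copy
    ortholog locus.  Returns the residual interval set and its size in bp.
    """
    by_contig: IntervalSet = {}
    for h in hits:
        iv = h.subject_interval
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    loci: IntervalSet = {}
    for iv in complete_busco_intervals:
        loci.setdefault(iv.contig, []).append((iv.start, iv.end))
    residual: IntervalSet = {}
    residual_bases = 0
    for contig, ivs in by_contig.items():
        rem = subtract_intervals(merge_intervals(ivs), loci.get(contig, []))
        if rem:
            residual[contig] = rem
            residual_bases += total_length(rem)
    return residual, residual_bases


def _repeat_priority(hit: RepeatHit) -> tuple:
    return (
        hit.score,
        -hit.interval.start,
        -hit.interval.end,
        tuple(-ord(c) for c in hit.family),
    )


def intersect_with_repeats(
    interval_set: IntervalSet, repeats: Sequence[RepeatHit]
) -> CategoryBaseCounts:
    """Attribute every residual base to the category of the overlapping
    repeat annotation (highest annotation score wins; ties broken by
    earlier interval then family name); unannotated bases are counted
    separately.  Conservation: categories + unannotated = total."""
    bases = {c: 0 for c in CATEGORIES}
    unannotated = 0
    total = 0
    reps_by_contig: Dict[str, List[RepeatHit]] = {}
    for r in repeats:
        reps_by_contig.setdefault(r.interval.contig, []).append(r)
    for contig, segments in interval_set.items():
        total += total_length(merge_intervals(segments))
        anns = [
            ((r.interval.start, r.interval.end), r)
            for r in reps_by_contig.get(contig, [])
        ]
        counts = assign_by_priority(segments, anns, _repeat_priority)
        for payload, n in counts.items():
            if payload is None:
                unannotated += n
            else:
                bases[payload.category] += n
    return CategoryBaseCounts(
        bases=bases, unannotated_bases=unannotated, total_bases=total
    )


# ------------------------------------------------------ per-gene chain

def quantify_te_associated_busco(
    busco_id: str,
    genome: GenomeSequenceSet,
    busco_table: Sequence[BuscoRecord],
    repeats: Sequence[RepeatHit],
    params: SearchParams = SearchParams(),
    external_hits: Optional[Sequence[SearchHit]] = None,
) -> Tuple[List[SearchHit], CategoryBaseCounts]:
    """Full search -> filter -> subtract -> intersect chain for one gene.

    With ``backend='external_table'`` the caller supplies pre-computed
    tabular hits and the builtin search is skipped; the downstream
    accounting is identical either way.
    """
    record = next(
        (b for b in busco_table if b.busco_id == busco_id and b.interval),
        None,
    )
    if record is None:
        raise LookupError(f"no located BUSCO {busco_id!r} in the table")
    if params.backend == "external_table":
        if external_hits is None:
            raise ParameterError(
                "backend='external_table' requires external_hits"
            )
        raw_hits = list(external_hits)
    else:
        query = genome.fetch(record.interval)
        raw_hits = seed_extend_search(query, genome, params, query_id=busco_id)
    kept = filter_hits(raw_hits, params)
    complete_loci = [
        b.interval
        for b in busco_table
        if b.status == "Complete" and b.interval is not None
    ]
    residual, _ = subtract_busco_loci(kept, complete_loci)
    counts = intersect_with_repeats(residual, repeats)
    return kept, counts


def reference_contrast(
    busco_id: str,
    inflated_query: str,
    reference_query: str,
    genome: GenomeSequenceSet,
    busco_table: Sequence[BuscoRecord],
    repeats: Sequence[RepeatHit],
    params: SearchParams = SearchParams(),
) -> ContrastResult:
    """Quantify both queries against the SAME (inflated) assembly.

    The reference query is the homologous gene from a species lacking the
    repeat fragment; the drop in residual bases shows the excess hits come
    from the fragment.
    """
    if not inflated_query or not reference_query:
        raise ParameterError("both query sequences must be non-empty")
    totals = []
    complete_loci = [
        b.interval
        for b in busco_table
        if b.status == "Complete" and b.interval is not None
    ]
    for query in (inflated_query, reference_query):
        raw = seed_extend_search(query, genome, params, query_id=busco_id)
        kept = filter_hits(raw, params)
        _, residual_bases = subtract_busco_loci(kept, complete_loci)
        totals.append(residual_bases)
    return ContrastResult(
        busco_id=busco_id,
        inflated_total_bases=totals[0],
        reference_total_bases=totals[1],
    )


# -------------------------------------------------- pairwise validation

@dataclass(frozen=True)
class AlignParams:
    match_score: float = 1.0
    mismatch_score: float = -2.0
    gap_open: float = 5.0
    gap_extend: float = 1.0
    min_gap: int = 30
    length_cap: int = 50_000


def _alignment_gaps_on_query(
    alignment, query_len: int
) -> List[Tuple[int, int]]:
    """Segments of the (inflated) query not matched by the reference."""
    q_blocks = alignment.aligned[0]  # blocks on the first (target) sequence
    gaps: List[Tuple[int, int]] = []
    prev_end = 0
    for qs, qe in q_blocks:
        if qs > prev_end:
            gaps.append((int(prev_end), int(qs)))
        prev_end = int(qe)
    if prev_end < query_len:
        gaps.append((prev_end, query_len))
    return gaps


def pairwise_validate(
    busco_id: str,
    inflated_seq: str,
    reference_seq: str,
    flagged_regions: Sequence[Tuple[int, int]],
    params: AlignParams = AlignParams(),
) -> ValidationVerdict:
    """Globally align the inflated gene against its reference ortholog and
    test whether a reference gap falls on a flagged high-coverage region.

    ``flagged_regions`` are (start, end) in the inflated gene's local
    coordinates.  The verdict is true iff an unaligned query segment of at
    least ``min_gap`` bp overlaps a flagged region by >= 50% of the region
    or >= 100 bp.
    """
    if len(inflated_seq) > params.length_cap or \
            len(reference_seq) > params.length_cap:
        raise ParameterError(
            f"sequence exceeds length cap {params.length_cap}; use a "
            "local-alignment workflow for sequences this long"
        )
    if not inflated_seq or not reference_seq:
        return ValidationVerdict(busco_id, False, False, 0)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    alignment = aligner.align(inflated_seq.upper(), reference_seq.upper())[0]
    gaps = [
        (s, e)
        for s, e in _alignment_gaps_on_query(alignment, len(inflated_seq))
        if e - s >= params.min_gap
    ]
    verdict = False
    for rs, re_ in flagged_regions:
        region_len = re_ - rs
        for gs, ge in gaps:
            ov = min(ge, re_) - max(gs, rs)
            if ov > 0 and (ov >= 0.5 * region_len or ov >= 100):
                verdict = True
    largest = max((e - s for s, e in gaps), default=0)
    return ValidationVerdict(
        busco_id=busco_id,
        aligned=True,
        gap_overlaps_flagged_region=verdict,
        largest_unaligned_query_segment=largest,
    )
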