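"""Readers and writers for the external text formats the pipeline touches.

External dialects and their coordinate conventions:

==========================  =============================
format                      external coordinates
==========================  =============================
FASTA                       n/a
BUSCO full_table TSV        1-based inclusive
RepeatMasker ``.out``       1-based inclusive
BLAST tabular (12 columns)  1-based inclusive
per-base depth TSV          1-based positions
bedGraph / BED              0-based half-open
==========================  =============================

Everything is converted to 0-based half-open on read and back on write, so
conversion happens at exactly one site per format.  All writers are
bit-stable: identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

from .core import (
    BuscoRecord,
    ConsistencyError,
    CoverageTrack,
    FormatError,
    GenomeSequenceSet,
    GenomicInterval,
    RepeatHit,
    SearchHit,
)
from .repeat_landscape import map_category

logger = logging.getLogger(__name__)

_ACGTN = set("ACGTN")


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str) -> GenomeSequenceSet:
    """Read a (possibly softmasked) FASTA into a GenomeSequenceSet.

    Sequences are uppercased; characters outside A/C/G/T/N become N (the
    replacement count is logged).  Record ids are the token up to the first
    whitespace.
    """
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: empty file")
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path}: line 1: expected '>'")
    sequences: Dict[str, str] = {}
    n_replaced = 0
    for i, rec in enumerate(SeqIO.parse(path, "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FormatError(f"{path}: record {i}: empty id")
        if rec.id in sequences:
            raise FormatError(f"{path}: record {i}: duplicate id {rec.id!r}")
        if len(seq) == 0:
            raise FormatError(f"{path}: record {i}: zero-length sequence")
        bad = [c for c in set(seq) if c not in _ACGTN]
        if bad:
            for c in bad:
                n_replaced += seq.count(c)
                seq = seq.replace(c, "N")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    if n_replaced:
        logger.info("%s: replaced %d non-ACGTN characters with N",
                    path, n_replaced)
    return GenomeSequenceSet(sequences)


def write_fasta(genome: GenomeSequenceSet, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in genome.contigs:
            fh.write(f">{contig}\n")
            seq = genome.sequence(contig)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------ BUSCO full_table TSV

_V3_COLUMNS = 7   # id, status, contig, start, end, score, length
_V5_COLUMNS = 10  # id, status, contig, start, end, strand, score, length, url, desc


def read_busco_full_table(path: str) -> List[BuscoRecord]:
    """Parse a BUSCO full_table (v3 or v5 column dialect, sniffed per row).

    Coordinates become 0-based half-open; rows whose start exceeds their end
    are strand-normalized (coordinates swapped, strand set to ``-``).
    """
    records: List[BuscoRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            busco_id, status = fields[0], fields[1]
            if status == "Missing":
                records.append(BuscoRecord(busco_id, status, None))
                continue
            if len(fields) < 5:
                raise FormatError(
                    f"{path}: line {lineno}: missing coordinates for "
                    f"{status} row"
                )
            contig = fields[2]
            try:
                start = int(fields[3])
                end = int(fields[4])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric coordinate"
                ) from exc
            strand = "."
            if len(fields) >= _V5_COLUMNS or (
                len(fields) >= 6 and fields[5] in "+-"
            ):
                # v5 dialect carries an explicit strand column
                strand = fields[5] if fields[5] in "+-" else "."
                score_field, length_field = 6, 7
            else:
                score_field, length_field = 5, 6
            if start > end:
                start, end = end, start
                strand = "-"
            score = float(fields[score_field]) if len(fields) > score_field else 0.0
            length = int(float(fields[length_field])) if len(fields) > length_field else end - start + 1
            records.append(
                BuscoRecord(
                    busco_id,
                    status,
                    GenomicInterval(contig, start - 1, end, strand),
                    score=score,
                    length=length,
                )
            )
    return records


def write_busco_full_table(records: Sequence[BuscoRecord], path: str) -> None:
    """Write the 7-column (v3) full_table dialect."""
    with open(path, "w") as fh:
        fh.write("# Busco id\tStatus\tContig\tStart\tEnd\tScore\tLength\n")
        for rec in records:
            if rec.status == "Missing":
                fh.write(f"{rec.busco_id}\tMissing\n")
                continue
            iv = rec.interval
            start, end = iv.start + 1, iv.end
            if iv.strand == "-":
                start, end = end, start
            fh.write(
                f"{rec.busco_id}\t{rec.status}\t{iv.contig}\t{start}\t{end}"
                f"\t{rec.score:g}\t{rec.length}\n"
            )


# ------------------------------------------------- RepeatMasker .out

_RM_HEADER = (
    "   SW   perc perc perc  query      position in query     matching"
    "       repeat              position in repeat\n"
    "score   div. del. ins.  sequence   begin  end    (left)  repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path: str) -> List[RepeatHit]:
    """Parse the RepeatMasker ``.out`` dialect (3 header lines then data).

    ``C`` orientation becomes strand ``-``; 1-based inclusive coordinates
    become 0-based half-open; categories are assigned via
    :func:`tebusco.repeat_landscape.map_category`.
    """
    hits: List[RepeatHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise FormatError(f"{path}: line {lineno}: short row")
        try:
            score = float(fields[0])
            div = float(fields[1])
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise FormatError(
                f"{path}: line {lineno}: non-numeric field"
            ) from exc
        contig = fields[4]
        strand = "-" if fields[8] == "C" else "+"
        family = fields[9]
        raw_class = fields[10]
        hits.append(
            RepeatHit(
                interval=GenomicInterval(contig, begin - 1, end, strand),
                family=family,
                raw_class=raw_class,
                category=map_category(raw_class),
                divergence=div,
                score=score,
            )
        )
    return hits


def write_repeatmasker_out(hits: Sequence[RepeatHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, h in enumerate(hits, start=1):
            iv = h.interval
            orient = "C" if iv.strand == "-" else "+"
            fh.write(
                f"{h.score:7.0f} {h.divergence:5.1f}  0.0  0.0  {iv.contig}"
                f" {iv.start + 1} {iv.end} (0) {orient} {h.family}"
                f" {h.raw_class} 1 {iv.end - iv.start} (0) {i}\n"
            )


# ------------------------------------------------ BLAST tabular hits

def read_tabular_hits(path: str) -> List[SearchHit]:
    """Read 12-column tabular search output (BLAST outfmt 6 dialect)."""
    hits: List[SearchHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, "
                    f"got {len(fields)}"
                )
            (qid, sid, pident, length, mismatch, _gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = fields
            qs, qe = int(qstart), int(qend)
            ss, se = int(sstart), int(send)
            strand = "+"
            if ss > se:
                ss, se = se, ss
                strand = "-"
            hits.append(
                SearchHit(
                    query_id=qid,
                    query_start=qs - 1,
                    query_end=qe,
                    subject_interval=GenomicInterval(sid, ss - 1, se, strand),
                    percent_identity=float(pident),
                    alignment_length=int(length),
                    e_value=float(evalue),
                    bit_score=float(bitscore),
                    mismatches=int(mismatch),
                )
            )
    return hits


def write_tabular_hits(hits: Sequence[SearchHit], path: str) -> None:
    with open(path, "w") as fh:
        for h in hits:
            iv = h.subject_interval
            ss, se = iv.start + 1, iv.end
            if iv.strand == "-":
                ss, se = se, ss
            fh.write(
                f"{h.query_id}\t{iv.contig}\t{h.percent_identity:.2f}"
                f"\t{h.alignment_length}\t{h.mismatches}\t0"
                f"\t{h.query_start + 1}\t{h.query_end}\t{ss}\t{se}"
                f"\t{h.e_value:.2g}\t{h.bit_score:.1f}\n"
            )


# ------------------------------------------------------- depth tracks

def read_depth(path: str, genome: GenomeSequenceSet) -> CoverageTrack:
    """Read a per-base depth table bound to ``genome``'s contig lengths.

    Accepts the 3-column TSV dialect (contig, 1-based position, depth) and
    the 4-column bedGraph dialect (contig, 0-based start, end, depth),
    sniffed per row by column count.  Positions absent from the file get
    depth 0.
    """
    depths = {
        contig: np.zeros(genome.length(contig), dtype=np.int64)
        for contig in genome.contigs
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            contig = fields[0]
            if contig not in depths:
                raise ConsistencyError(
                    f"{path}: line {lineno}: unknown contig {contig!r}"
                )
            arr = depths[contig]
            if len(fields) == 3:
                pos = int(fields[1])
                if not 1 <= pos <= arr.size:
                    raise ConsistencyError(
                        f"{path}: line {lineno}: position {pos} exceeds "
                        f"contig {contig!r} length {arr.size}"
                    )
                arr[pos - 1] = int(fields[2])
            elif len(fields) == 4:
                start, end = int(fields[1]), int(fields[2])
                if not 0 <= start < end <= arr.size:
                    raise ConsistencyError(
                        f"{path}: line {lineno}: interval [{start},{end}) "
                        f"outside contig {contig!r} length {arr.size}"
                    )
                arr[start:end] = int(fields[3])
            else:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 or 4 columns"
                )
    return CoverageTrack(depths)


def write_depth(track: CoverageTrack, path: str) -> None:
    """Write the 3-column TSV dialect; zero-depth positions are omitted."""
    with open(path, "w") as fh:
        for contig in track.contigs:
            arr = track.depth(contig)
            for pos in np.nonzero(arr)[0]:
                fh.write(f"{contig}\t{pos + 1}\t{arr[pos]}\n")


# --------------------------------------------------------------- BED

def write_bed(
    intervals: Iterable[Tuple[GenomicInterval, str]], path: str
) -> None:
    """Write (interval, name) pairs as 4-column BED."""
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\n")
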