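"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open everywhere inside the package; the
readers/writers in :mod:`tebusco.io_formats` convert to and from the
1-based external dialects at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional

import numpy as np

VALID_BASES = set("ACGTN")
BUSCO_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")


class TebuscoError(Exception):
    """Base class for package errors."""


class FormatError(TebuscoError):
    """Malformed input file."""


class ConsistencyError(TebuscoError):
    """Objects refer to different assemblies / contigs."""


class ParameterError(TebuscoError, ValueError):
    """Invalid parameter value."""


class PlacementError(TebuscoError):
    """Synthetic feature placement is infeasible."""


class BaselineError(TebuscoError):
    """No usable positions for a coverage baseline."""


class EstimationError(TebuscoError):
    """Genome-size estimation impossible (no positive-depth mass)."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class GenomeSequenceSet:
    """Ordered collection of named contig sequences (uppercase A/C/G/T/N)."""

    def __init__(self, sequences: Mapping[str, str]):
        self._sequences: Dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise FormatError("empty contig id")
            if name in self._sequences:
                raise FormatError(f"duplicate contig id {name!r}")
            if len(seq) == 0:
                raise FormatError(f"zero-length contig {name!r}")
            self._sequences[name] = seq.upper()
        # lazily populated 2-bit encodings used by the search backend
        self._encoded: Dict[str, np.ndarray] = {}

    def __contains__(self, contig: str) -> bool:
        return contig in self._sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self._sequences)

    def __len__(self) -> int:
        return len(self._sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeSequenceSet):
            return NotImplemented
        return self._sequences == other._sequences

    @property
    def contigs(self) -> List[str]:
        return list(self._sequences)

    def sequence(self, contig: str) -> str:
        return self._sequences[contig]

    def length(self, contig: str) -> int:
        return len(self._sequences[contig])

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._sequences.values())

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self._sequences[interval.contig]
        if interval.end > len(seq):
            raise ConsistencyError(
                f"interval {interval} exceeds contig length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def encoded(self, contig: str) -> np.ndarray:
        """2-bit base encoding (A=0, C=1, G=2, T=3, N and others=4)."""
        if contig not in self._encoded:
            self._encoded[contig] = encode_sequence(self._sequences[contig])
        return self._encoded[contig]


_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BuscoRecord:
    """One single-copy-ortholog annotation row."""

    busco_id: str
    status: str
    interval: Optional[GenomicInterval]
    score: float = 0.0
    length: int = 0

    def __post_init__(self) -> None:
        if self.status not in BUSCO_STATUSES:
            raise FormatError(f"unknown BUSCO status {self.status!r}")
        if self.status == "Missing" and self.interval is not None:
            raise FormatError("Missing BUSCO must not carry an interval")
        if self.status != "Missing" and self.interval is None:
            raise FormatError(
                f"{self.status} BUSCO {self.busco_id} lacks coordinates"
            )


@dataclass(frozen=True)
class RepeatHit:
    """One repeat-annotation interval (RepeatMasker .out row)."""

    interval: GenomicInterval
    family: str
    raw_class: str
    category: str
    divergence: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 100.0:
            raise FormatError(
                f"divergence {self.divergence} outside [0, 100]"
            )


@dataclass(frozen=True)
class SearchHit:
    """One (ungapped) nucleotide search hit, BLAST-tabular compatible."""

    query_id: str
    query_start: int
    query_end: int
    subject_interval: GenomicInterval
    percent_identity: float
    alignment_length: int
    e_value: float
    bit_score: float
    mismatches: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise FormatError("identity outside [0, 100]")
        if self.e_value < 0:
            raise FormatError("negative e-value")


class CoverageTrack:
    """Per-contig integer read depth bound to a genome's contig lengths."""

    def __init__(self, depths: Mapping[str, np.ndarray]):
        self._depths: Dict[str, np.ndarray] = {}
        for contig, arr in depths.items():
            a = np.asarray(arr, dtype=np.int64)
            if a.ndim != 1:
                raise ValueError("depth array must be 1-D")
            if (a < 0).any():
                raise ValueError(f"negative depth on contig {contig!r}")
            self._depths[contig] = a
        self.total_mapped_bases = int(
            sum(int(a.sum()) for a in self._depths.values())
        )

    def __contains__(self, contig: str) -> bool:
        return contig in self._depths

    @property
    def contigs(self) -> List[str]:
        return list(self._depths)

    def depth(self, contig: str) -> np.ndarray:
        return self._depths[contig]

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        arr = self._depths[interval.contig]
        if interval.end > arr.size:
            raise ConsistencyError(
                f"interval {interval} exceeds track length {arr.size}"
            )
        return arr[interval.start : interval.end]

    def check_bound(self, genome: GenomeSequenceSet) -> None:
        for contig in self._depths:
            if contig not in genome:
                raise ConsistencyError(f"track contig {contig!r} not in genome")
            if self._depths[contig].size != genome.length(contig):
                raise ConsistencyError(
                    f"track length mismatch on contig {contig!r}"
                )

    def all_positions(self) -> np.ndarray:
        """Concatenated depths over all contigs (order = insertion order)."""
        if not self._depths:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([self._depths[c] for c in self._depths])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return self.contigs == other.contigs and all(
            np.array_equal(self._depths[c], other._depths[c])
            for c in self._depths
        )
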