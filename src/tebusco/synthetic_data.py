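"""Synthetic genomes with planted TE families and TE-gene insertions.

The generator emulates the data regime the pipeline is built for: a
multi-contig assembly carrying single-copy-ortholog gene models, several
repeat families with many genomic copies whose per-copy divergence from the
family consensus follows a configurable distribution (recent bursts = low
divergence, ancient bursts = high divergence), TE fragments planted inside
or immediately adjacent to a known subset of genes, and a read-depth track
in which positions inside multi-copy repeat sequence are inflated in
proportion to family copy number (the multi-mapping pileup that makes
TE-associated genes detectable), with Poisson noise elsewhere.

Every output is a deterministic function of (config, seed); the ground
truth is emitted alongside the standard-format files so each downstream
stage can be scored against it.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from . import io_formats
from .core import (
    BuscoRecord,
    ConsistencyError,
    CoverageTrack,
    GenomeSequenceSet,
    GenomicInterval,
    ParameterError,
    PlacementError,
    RepeatHit,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: distribution spec tuples: ("point", v) | ("uniform", lo, hi) |
#: ("normal", mean, sd)  (normal is truncated to the legal support)
Distribution = Tuple


def _sample_dist(dist: Distribution, rng: np.random.Generator, size: int,
                 lo: float, hi: float) -> np.ndarray:
    kind = dist[0]
    if kind == "point":
        out = np.full(size, float(dist[1]))
    elif kind == "uniform":
        out = rng.uniform(float(dist[1]), float(dist[2]), size)
    elif kind == "normal":
        out = rng.normal(float(dist[1]), float(dist[2]), size)
    else:
        raise ParameterError(f"unknown distribution kind {kind!r}")
    return np.clip(out, lo, hi)


@dataclass(frozen=True)
class FamilySpec:
    """One simulated repeat family."""

    family_name: str
    category: str
    consensus_length: int
    copy_number: int
    divergence: Distribution = ("point", 0.05)

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ParameterError("copy_number must be >= 0")
        if self.consensus_length <= 0:
            raise ParameterError("consensus_length must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard benchmark dataset: a 2 Mb assembly on 4
    contigs with 200 complete single-copy genes of ~1.5 kb, one 50-copy
    LINE family (2 kb consensus, per-copy divergence ~ N(0.05, 0.02)
    truncated at 0), 20% of genes receiving a 200-1,000 bp internal family
    fragment, and 10x mean haploid depth.
    """

    genome_length: int = 2_000_000
    n_contigs: int = 4
    n_genes: int = 200
    gene_length: Distribution = ("uniform", 1200, 1800)
    te_families: Tuple[FamilySpec, ...] = (
        FamilySpec("LINE-1_sim", "LINE", 2000, 50, ("normal", 0.05, 0.02)),
    )
    te_associated_fraction: float = 0.2
    insert_length: Distribution = ("uniform", 200, 1000)
    insert_placement: str = "internal"  # internal | adjacent | mixed
    adjacency_window: int = 100
    base_depth: float = 10.0
    read_length: int = 150
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.te_associated_fraction <= 1.0:
            raise ParameterError("te_associated_fraction outside [0, 1]")
        if self.insert_placement not in ("internal", "adjacent", "mixed"):
            raise ParameterError(
                f"unknown insert_placement {self.insert_placement!r}"
            )
        if self.n_contigs < 1 or self.n_genes < 0:
            raise ParameterError("n_contigs >= 1 and n_genes >= 0 required")

    def config_hash(self) -> str:
        payload = repr(asdict(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class PlacedCopy:
    """One realized repeat copy (intergenic copy or planted gene insert)."""

    interval: GenomicInterval
    family_name: str
    realized_divergence: float  # measured mismatch fraction vs consensus
    consensus_start: int        # fragment coordinates on the consensus
    consensus_end: int
    gene_id: Optional[str] = None  # set for planted gene inserts


@dataclass
class SimulationTruth:
    """Ground truth emitted next to the standard-format files."""

    family_consensus: Dict[str, str]
    placed_copies: List[PlacedCopy]
    te_associated_genes: Dict[str, List[GenomicInterval]]
    non_associated_genes: List[str]

    def copies_of(self, family_name: str) -> List[PlacedCopy]:
        return [c for c in self.placed_copies if c.family_name == family_name]

    def family_copy_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for c in self.placed_copies:
            counts[c.family_name] = counts.get(c.family_name, 0) + 1
        return counts


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def mutate_copy(
    consensus: str, divergence: float, rng: np.random.Generator
) -> Tuple[str, float]:
    """Substitute bases of ``consensus`` per site at rate ``divergence``.

    Substitutions go to a uniformly random different base; indels are not
    introduced, so the realized divergence (returned alongside the mutated
    sequence) is exactly the mismatch fraction against the consensus.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ParameterError(f"divergence {divergence} outside [0, 0.5]")
    if not consensus:
        raise ParameterError("empty consensus")
    codes = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(codes.size) < divergence
    n_hit = int(hit.sum())
    if n_hit:
        idx = {ord(b): i for i, b in enumerate("ACGT")}
        cur = np.array([idx[c] for c in codes[hit]])
        # shift by 1..3 positions in base space => always a different base
        new = (cur + rng.integers(1, 4, n_hit)) % 4
        codes[hit] = _BASES[new]
    realized = n_hit / codes.size
    return codes.tobytes().decode("ascii"), realized


def _split_contigs(total: int, n: int) -> List[int]:
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


def _place_non_overlapping(
    rng: np.random.Generator, contig_len: int, lengths: Sequence[int],
    contig_name: str,
) -> List[int]:
    """Uniform non-overlapping placement via stick breaking.

    Free space (contig length minus total feature length) is split into
    random gaps; features keep their (already shuffled) order.
    """
    total = int(np.sum(lengths)) if len(lengths) else 0
    free = contig_len - total
    if free < 0:
        raise PlacementError(
            f"contig {contig_name!r} overfull: {total} feature bp into "
            f"{contig_len} bp"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    starts = []
    offset = 0
    for cut, ln in zip(cuts, lengths):
        starts.append(int(cut) + offset)
        offset += ln
    return starts


def simulate_genome(
    config: SimulationConfig,
) -> Tuple[GenomeSequenceSet, List[BuscoRecord], List[RepeatHit], SimulationTruth]:
    """Generate a genome plus gene table, repeat annotation and truth.

    Background sequence is i.i.d. uniform A/C/G/T.  Genes (all status
    Complete) and intergenic repeat copies are placed uniformly without
    overlap; a ``te_associated_fraction`` subset of genes additionally
    receives a mutated family fragment inside the gene body (or abutting
    it, for adjacent placement, in which case the emitted gene interval is
    extended over the insert — mimicking ortholog annotations that
    inadvertently include adjacent repeat sequence).
    """
    rng = np.random.default_rng(config.seed)
    contig_lengths = _split_contigs(config.genome_length, config.n_contigs)
    contig_names = [f"contig_{i + 1}" for i in range(config.n_contigs)]

    # family consensus sequences
    consensus = {
        f.family_name: random_sequence(rng, f.consensus_length)
        for f in config.te_families
    }

    # gene lengths and TE-associated subset
    gene_lengths = np.rint(
        _sample_dist(config.gene_length, rng, config.n_genes, 200, 1e9)
    ).astype(int)
    gene_ids = [f"simbusco{i + 1:04d}" for i in range(config.n_genes)]
    n_assoc = int(round(config.te_associated_fraction * config.n_genes))
    assoc_idx = set(
        rng.choice(config.n_genes, size=n_assoc, replace=False).tolist()
    ) if n_assoc else set()

    # per-gene insert plans (family, fragment, placement mode)
    copy_weights = np.array(
        [max(f.copy_number, 1) for f in config.te_families], dtype=float
    )
    insert_plan: Dict[int, Tuple[FamilySpec, int, str]] = {}
    for gi in sorted(assoc_idx):
        if not config.te_families:
            break
        fam = config.te_families[
            int(rng.choice(len(config.te_families),
                           p=copy_weights / copy_weights.sum()))
        ]
        ins_len = int(np.rint(_sample_dist(
            config.insert_length, rng, 1, 50, fam.consensus_length
        )[0]))
        if config.insert_placement == "mixed":
            mode = "internal" if rng.random() < 0.5 else "adjacent"
        else:
            mode = config.insert_placement
        if mode == "internal":
            ins_len = min(ins_len, int(gene_lengths[gi]) - 100)
        insert_plan[gi] = (fam, ins_len, mode)
    if not config.te_families:
        assoc_idx = set()

    # build the feature list: genes (with any adjacent insert appended) and
    # intergenic family copies
    features: List[Tuple[str, int, object]] = []  # (kind, length, payload)
    for gi in range(config.n_genes):
        length = int(gene_lengths[gi])
        if gi in insert_plan and insert_plan[gi][2] == "adjacent":
            length += insert_plan[gi][1]
        features.append(("gene", length, gi))
    for fam in config.te_families:
        for ci in range(fam.copy_number):
            features.append(("copy", fam.consensus_length, fam))

    total_feature_bp = sum(length for _, length, _ in features)
    if total_feature_bp > config.genome_length:
        raise PlacementError(
            f"total feature length {total_feature_bp} exceeds genome "
            f"length {config.genome_length}"
        )

    # assign features to contigs (length-weighted), retry on overfull contigs
    weights = np.array(contig_lengths, dtype=float)
    weights /= weights.sum()
    for attempt in range(25):
        assignment = rng.choice(config.n_contigs, size=len(features), p=weights)
        per_contig_bp = np.zeros(config.n_contigs, dtype=np.int64)
        for fi, ci in enumerate(assignment):
            per_contig_bp[ci] += features[fi][1]
        if (per_contig_bp <= np.array(contig_lengths)).all():
            break
    else:
        worst = int(np.argmax(per_contig_bp - np.array(contig_lengths)))
        raise PlacementError(
            f"contig {contig_names[worst]!r} overfull after retries"
        )

    # background sequence
    contig_seqs = {
        name: bytearray(random_sequence(rng, ln), "ascii")
        for name, ln in zip(contig_names, contig_lengths)
    }

    gene_records: List[BuscoRecord] = [None] * config.n_genes  # type: ignore
    placed_copies: List[PlacedCopy] = []
    te_associated: Dict[str, List[GenomicInterval]] = {}

    for ci, cname in enumerate(contig_names):
        idxs = [fi for fi in range(len(features)) if assignment[fi] == ci]
        rng.shuffle(idxs)
        lengths = [features[fi][1] for fi in idxs]
        starts = _place_non_overlapping(rng, contig_lengths[ci], lengths, cname)
        for fi, start in zip(idxs, starts):
            kind, length, payload = features[fi]
            if kind == "copy":
                fam: FamilySpec = payload  # type: ignore
                div = float(_sample_dist(fam.divergence, rng, 1, 0.0, 0.5)[0])
                seq, realized = mutate_copy(consensus[fam.family_name], div, rng)
                contig_seqs[cname][start : start + length] = seq.encode()
                placed_copies.append(
                    PlacedCopy(
                        interval=GenomicInterval(cname, start, start + length, "+"),
                        family_name=fam.family_name,
                        realized_divergence=realized,
                        consensus_start=0,
                        consensus_end=fam.consensus_length,
                    )
                )
            else:
                gi: int = payload  # type: ignore
                gene_len = int(gene_lengths[gi])
                gene_start, gene_end = start, start + gene_len
                record_end = gene_end
                if gi in insert_plan:
                    fam, ins_len, mode = insert_plan[gi]
                    frag_start = int(rng.integers(
                        0, fam.consensus_length - ins_len + 1
                    ))
                    fragment = consensus[fam.family_name][
                        frag_start : frag_start + ins_len
                    ]
                    div = float(_sample_dist(fam.divergence, rng, 1, 0.0, 0.5)[0])
                    seq, realized = mutate_copy(fragment, div, rng)
                    if mode == "internal":
                        off = int(rng.integers(0, gene_len - ins_len + 1))
                        ins_start = gene_start + off
                    else:  # adjacent: abuts the gene end
                        ins_start = gene_end
                        record_end = gene_end + ins_len
                    ins_iv = GenomicInterval(
                        cname, ins_start, ins_start + ins_len, "+"
                    )
                    contig_seqs[cname][ins_start : ins_start + ins_len] = \
                        seq.encode()
                    placed_copies.append(
                        PlacedCopy(
                            interval=ins_iv,
                            family_name=fam.family_name,
                            realized_divergence=realized,
                            consensus_start=frag_start,
                            consensus_end=frag_start + ins_len,
                            gene_id=gene_ids[gi],
                        )
                    )
                    te_associated.setdefault(gene_ids[gi], []).append(ins_iv)
                # v3 full_table carries no strand column; use "." so the
                # emitted table round-trips exactly
                iv = GenomicInterval(cname, gene_start, record_end, ".")
                gene_records[gi] = BuscoRecord(
                    gene_ids[gi], "Complete", iv,
                    score=100.0, length=record_end - gene_start,
                )

    truth = SimulationTruth(
        family_consensus=consensus,
        placed_copies=placed_copies,
        te_associated_genes=te_associated,
        non_associated_genes=[
            gene_ids[i] for i in range(config.n_genes) if i not in assoc_idx
        ],
    )
    genome = GenomeSequenceSet(
        {name: bytes(contig_seqs[name]).decode("ascii")
         for name in contig_names}
    )
    cat_by_family = {f.family_name: f.category for f in config.te_families}
    raw_by_family = {
        f.family_name: (f.category if f.category in
                        ("LINE", "SINE", "LTR", "DNA", "Satellite")
                        else f.category)
        for f in config.te_families
    }
    repeat_truth = [
        RepeatHit(
            interval=c.interval,
            family=c.family_name,
            raw_class=raw_by_family[c.family_name],
            category=_canonical(cat_by_family[c.family_name]),
            divergence=round(c.realized_divergence * 100.0, 1),
            score=float(len(c.interval)),
        )
        for c in placed_copies
    ]
    return genome, list(gene_records), repeat_truth, truth


def _canonical(category: str) -> str:
    from .repeat_landscape import CATEGORIES, map_category
    return category if category in CATEGORIES else map_category(category)


def simulate_coverage(
    genome: GenomeSequenceSet,
    truth: SimulationTruth,
    base_depth: float,
    seed: int,
    read_length: int = 150,
) -> CoverageTrack:
    """Simulate a read-mapping depth track under the multiplicity model.

    Depth at position p is Poisson(base_depth x m(p)), where the
    multiplicity m(p) equals the number of genomic copies of the family
    whose copy covers p (multi-mapped reads pile up on every copy), and 1
    elsewhere.  The draw is then smoothed with a read-length moving mean to
    mimic read-edge effects.
    """
    if base_depth < 0:
        raise ParameterError("base_depth must be >= 0")
    counts = truth.family_copy_counts()
    rng = np.random.default_rng(seed)
    depths: Dict[str, np.ndarray] = {}
    for contig in genome.contigs:
        n = genome.length(contig)
        mult = np.ones(n, dtype=float)
        for copy in truth.placed_copies:
            if copy.interval.contig != contig:
                continue
            if copy.interval.end > n:
                raise ConsistencyError(
                    f"truth interval {copy.interval} outside contig {contig!r}"
                )
            mult[copy.interval.start : copy.interval.end] = counts[
                copy.family_name
            ]
        raw = rng.poisson(base_depth * mult).astype(float)
        if read_length > 1:
            raw = uniform_filter1d(raw, size=read_length, mode="nearest")
        depths[contig] = np.rint(raw).astype(np.int64)
    return CoverageTrack(depths)


# ------------------------------------------------------------- file set

TRUTH_FILENAME = "truth.json"
MANIFEST_FILENAME = "manifest.tsv"


def write_dataset(
    directory: str,
    genome: GenomeSequenceSet,
    buscos: Sequence[BuscoRecord],
    repeats: Sequence[RepeatHit],
    truth: SimulationTruth,
    track: CoverageTrack,
    config: SimulationConfig,
) -> Dict[str, str]:
    """Write the complete simulated dataset to ``directory``.

    Emits genome FASTA, BUSCO full_table, RepeatMasker-dialect ``.out``,
    per-base depth TSV, a JSON truth sidecar and a manifest (file list,
    seed, config hash).  Returns {logical name: path}.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "genome": os.path.join(directory, "genome.fasta"),
        "busco_table": os.path.join(directory, "busco_full_table.tsv"),
        "repeats": os.path.join(directory, "repeats.out"),
        "depth": os.path.join(directory, "depth.tsv"),
        "truth": os.path.join(directory, TRUTH_FILENAME),
        "manifest": os.path.join(directory, MANIFEST_FILENAME),
    }
    io_formats.write_fasta(genome, paths["genome"])
    io_formats.write_busco_full_table(buscos, paths["busco_table"])
    io_formats.write_repeatmasker_out(repeats, paths["repeats"])
    io_formats.write_depth(track, paths["depth"])
    with open(paths["truth"], "w") as fh:
        json.dump(_truth_to_json(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(paths["manifest"], "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"config_hash\t{config.config_hash()}\n")
        for name in ("genome", "busco_table", "repeats", "depth", "truth"):
            fh.write(f"file:{name}\t{os.path.basename(paths[name])}\n")
    return paths


def _iv_to_json(iv: GenomicInterval) -> Dict:
    return {"contig": iv.contig, "start": iv.start, "end": iv.end,
            "strand": iv.strand}


def _iv_from_json(d: Dict) -> GenomicInterval:
    return GenomicInterval(d["contig"], d["start"], d["end"], d["strand"])


def _truth_to_json(truth: SimulationTruth) -> Dict:
    return {
        "family_consensus": truth.family_consensus,
        "placed_copies": [
            {
                "interval": _iv_to_json(c.interval),
                "family_name": c.family_name,
                "realized_divergence": c.realized_divergence,
                "consensus_start": c.consensus_start,
                "consensus_end": c.consensus_end,
                "gene_id": c.gene_id,
            }
            for c in truth.placed_copies
        ],
        "te_associated_genes": {
            gid: [_iv_to_json(iv) for iv in ivs]
            for gid, ivs in truth.te_associated_genes.items()
        },
        "non_associated_genes": truth.non_associated_genes,
    }


def read_truth(path: str) -> SimulationTruth:
    """Read the JSON truth sidecar written by :func:`write_dataset`."""
    with open(path) as fh:
        d = json.load(fh)
    return SimulationTruth(
        family_consensus=d["family_consensus"],
        placed_copies=[
            PlacedCopy(
                interval=_iv_from_json(c["interval"]),
                family_name=c["family_name"],
                realized_divergence=c["realized_divergence"],
                consensus_start=c["consensus_start"],
                consensus_end=c["consensus_end"],
                gene_id=c.get("gene_id"),
            )
            for c in d["placed_copies"]
        ],
        te_associated_genes={
            gid: [_iv_from_json(iv) for iv in ivs]
            for gid, ivs in d["te_associated_genes"].items()
        },
        non_associated_genes=list(d["non_associated_genes"]),
    )


def emit_reads(
    genome: GenomeSequenceSet,
    depth: float,
    read_length: int,
    seed: int,
    path: str,
) -> int:
    """Emit uniform error-free single-end FASTQ reads at ``depth``x.

    Convenience for users who want to run a real aligner; the pipeline's
    own tests never use it.  Returns the number of reads written.
    """
    rng = np.random.default_rng(seed)
    n_written = 0
    with open(path, "w") as fh:
        for contig in genome.contigs:
            seq = genome.sequence(contig)
            n_reads = int(np.ceil(depth * len(seq) / read_length))
            if len(seq) <= read_length:
                continue
            starts = rng.integers(0, len(seq) - read_length + 1, n_reads)
            for ri, s in enumerate(starts):
                fh.write(
                    f"@{contig}_{ri}\n{seq[s:s + read_length]}\n+\n"
                    f"{'I' * read_length}\n"
                )
                n_written += 1
    return n_written
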