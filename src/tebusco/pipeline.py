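"""End-to-end orchestration: detect -> quantify -> landscape -> genome size.

One dataset directory (genome FASTA, BUSCO full_table, RepeatMasker-dialect
``.out``, per-base depth TSV) in; one result directory (TSV tables, BED
exports, JSON summary + provenance) out.  Every stage is importable on its
own; this module only wires them together and writes files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

from . import __version__, coverage_busco, genome_size, io_formats, te_quantify
from .coverage_busco import ProfileParams, TEAssociationReport
from .repeat_landscape import (
    CATEGORIES,
    divergence_landscape,
    merge_repeat_runs,
    summarize_repeats,
)
from .te_quantify import SearchParams


@dataclass
class RunConfig:
    genome: str
    busco_table: str
    depth: str
    repeats: Optional[str] = None
    repeats_second_pass: Optional[str] = None
    out_dir: str = "results"
    species: str = "sample"
    profile: ProfileParams = field(default_factory=ProfileParams)
    search: SearchParams = field(default_factory=SearchParams)
    bin_width: float = 1.0
    kmer_k: int = 21
    seed: int = 0
    max_quantified_buscos: Optional[int] = None


def _sha1(path: str) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run every stage on one dataset and write the result directory.

    Returns the summary dictionary that is also written as JSON.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    genome = io_formats.read_fasta(config.genome)
    buscos = io_formats.read_busco_full_table(config.busco_table)
    track = io_formats.read_depth(config.depth, genome)
    repeats = (
        io_formats.read_repeatmasker_out(config.repeats)
        if config.repeats
        else []
    )
    if config.repeats_second_pass:
        second = io_formats.read_repeatmasker_out(config.repeats_second_pass)
        repeats = merge_repeat_runs(repeats, second)

    # --- stage: detect TE-associated BUSCOs
    report = coverage_busco.classify_te_associated(
        buscos, track, config.profile
    )
    _write_detection(report, config.out_dir)

    # --- stage: quantify repeat content per flagged gene
    flagged = report.flagged_ids()
    if config.max_quantified_buscos is not None:
        flagged = flagged[: config.max_quantified_buscos]
    per_busco_rows = []
    for busco_id in flagged:
        hits, counts = te_quantify.quantify_te_associated_busco(
            busco_id, genome, buscos, repeats, config.search
        )
        row = {
            "busco_id": busco_id,
            "n_hits": len(hits),
            "total_bases": counts.total_bases,
            "unannotated_bases": counts.unannotated_bases,
        }
        row.update({f"bases_{c}": counts.bases[c] for c in CATEGORIES})
        per_busco_rows.append(row)
    _write_tsv(
        os.path.join(config.out_dir, "te_quantification.tsv"), per_busco_rows
    )

    # --- stage: repeat summary and divergence landscape
    summary = summarize_repeats(repeats, genome.total_length)
    landscape = divergence_landscape(
        repeats, genome.total_length, config.bin_width
    )
    _write_tsv(
        os.path.join(config.out_dir, "repeat_summary.tsv"),
        [
            {
                "category": c,
                "bases": summary.bases[c],
                "proportion": summary.proportions[c],
            }
            for c in CATEGORIES
        ],
    )
    _write_tsv(
        os.path.join(config.out_dir, "repeat_landscape.tsv"),
        [
            {
                "category": c,
                "bin_start": float(landscape.bin_starts[bi]),
                "proportion": landscape.matrix[ci, bi],
            }
            for ci, c in enumerate(landscape.categories)
            for bi in range(landscape.bin_starts.size)
        ],
    )

    # --- stage: genome size
    hist = genome_size.depth_histogram(track)
    backmap = genome_size.estimate_size_backmap(hist)
    kmer_hist = genome_size.kmer_histogram(
        (genome.sequence(c) for c in genome.contigs), k=config.kmer_k
    )
    kmer_est = genome_size.estimate_size_kmer_peak(kmer_hist, read_mode=False)
    _write_tsv(
        os.path.join(config.out_dir, "genome_size.tsv"),
        [
            {
                "species": config.species,
                "method": est.method,
                "size_bp": est.size_bp,
                "peak": est.peak_depth,
            }
            for est in (backmap, kmer_est)
        ],
    )

    summary_row = {
        "species": config.species,
        "assembly_bp": genome.total_length,
        "backmap_size_bp": backmap.size_bp,
        "kmer_size_bp": kmer_est.size_bp,
        "n_busco_denominator": report.n_denominator,
        "n_te_associated": report.n_te_associated,
        "te_associated_fraction": report.fraction,
        "repeat_masked_proportion": summary.masked_proportion,
    }
    summary_row.update(
        {f"repeat_prop_{c}": summary.proportions[c] for c in CATEGORIES}
    )
    _write_tsv(
        os.path.join(config.out_dir, "species_summary.tsv"), [summary_row]
    )

    provenance = {
        "tebusco_version": __version__,
        "seed": config.seed,
        "profile_params": asdict(config.profile),
        "search_params": asdict(config.search),
        "bin_width": config.bin_width,
        "inputs": {
            name: {"path": path, "sha1": _sha1(path)}
            for name, path in (
                ("genome", config.genome),
                ("busco_table", config.busco_table),
                ("depth", config.depth),
                ("repeats", config.repeats),
            )
            if path
        },
    }
    with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary_row, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary_row


def _write_detection(report: TEAssociationReport, out_dir: str) -> None:
    rows = []
    bed_rows = []
    for busco_id, flag in report.flags.items():
        rows.append(
            {
                "busco_id": busco_id,
                "te_associated": int(flag.te_associated),
                "n_regions": len(flag.regions),
                "max_fold": max(
                    (r.mean_fold for r in flag.regions), default=0.0
                ),
            }
        )
        for r in flag.regions:
            bed_rows.append((r.interval, busco_id))
    _write_tsv(os.path.join(out_dir, "te_associated.tsv"), rows)
    io_formats.write_bed(
        bed_rows, os.path.join(out_dir, "high_coverage_regions.bed")
    )
    with open(os.path.join(out_dir, "detection_summary.json"), "w") as fh:
        json.dump(
            {
                "baseline": report.baseline,
                "denominator_mode": report.denominator_mode,
                "n_te_associated": report.n_te_associated,
                "n_denominator": report.n_denominator,
                "fraction": report.fraction,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")


def _write_tsv(path: str, rows: List[Dict[str, object]]) -> None:
    with open(path, "w") as fh:
        if not rows:
            fh.write("")
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(value: object) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)
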