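"""Benchmark experiments on synthetic data with known ground truth.

Each function sets up the standard study conditions for one question —
detector accuracy, quantifier fidelity, reference contrast, alignment
validation, genome-size recovery, landscape burst recovery, permutation
test calibration — runs the corresponding pipeline stage, and scores it
against the simulation truth.  The analysis drivers, the test suite and
the reproduction script all call these functions rather than re-wiring the
stages themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import association_stats, coverage_busco, genome_size, te_quantify
from .core import BuscoRecord, CoverageTrack, GenomeSequenceSet
from .coverage_busco import ProfileParams
from .repeat_landscape import divergence_landscape
from .synthetic_data import (
    FamilySpec,
    PlacedCopy,
    SimulationConfig,
    SimulationTruth,
    mutate_copy,
    random_sequence,
    simulate_coverage,
    simulate_genome,
)
from .te_quantify import AlignParams, SearchParams

#: 1C genome sizes (Mb) of the printed extremes of the flow-cytometry
#: panel: the smallest (a purse-case-building hydroptilid) and largest
#: (a limnephilid tube case-builder) measured caddisfly genomes.
PRINTED_1C_EXTREMES_MB = (154.0, 2129.0)


def genome_size_fold_range(
    sizes_mb: Sequence[float] = PRINTED_1C_EXTREMES_MB,
) -> float:
    """Fold range (max/min) of a set of 1C genome sizes."""
    sizes = [float(s) for s in sizes_mb]
    if not sizes or min(sizes) <= 0:
        raise ValueError("sizes must be positive")
    return max(sizes) / min(sizes)


# ------------------------------------------------------------ datasets

def make_benchmark_dataset(
    seed: int, config: Optional[SimulationConfig] = None
):
    """Standard benchmark dataset (see SimulationConfig defaults) at a seed.

    The coverage track uses an offset RNG stream so genome and track noise
    are independent.  Returns (config, genome, buscos, repeats, truth,
    track).
    """
    cfg = replace(config or SimulationConfig(), seed=seed)
    genome, buscos, repeats, truth = simulate_genome(cfg)
    track = simulate_coverage(
        genome, truth, cfg.base_depth, seed=seed + 100_000,
        read_length=cfg.read_length,
    )
    return cfg, genome, buscos, repeats, truth, track


# ----------------------------------------------------- detector scoring

@dataclass
class DetectorScore:
    recall: float
    fpr: float
    n_true_positive: int
    n_false_positive: int
    n_positive_truth: int
    n_negative_truth: int


def score_detector(
    report: coverage_busco.TEAssociationReport, truth: SimulationTruth
) -> DetectorScore:
    truth_pos = set(truth.te_associated_genes)
    truth_neg = set(truth.non_associated_genes)
    flagged = set(report.flagged_ids())
    tp = len(flagged & truth_pos)
    fp = len(flagged & truth_neg)
    return DetectorScore(
        recall=tp / len(truth_pos) if truth_pos else float("nan"),
        fpr=fp / len(truth_neg) if truth_neg else float("nan"),
        n_true_positive=tp,
        n_false_positive=fp,
        n_positive_truth=len(truth_pos),
        n_negative_truth=len(truth_neg),
    )


def detector_benchmark(
    seeds: Sequence[int],
    params: ProfileParams = ProfileParams(),
    config: Optional[SimulationConfig] = None,
) -> Tuple[float, float, List[DetectorScore]]:
    """Mean recall and false-positive rate of the TE-associated-BUSCO
    detector over independently simulated replicate datasets."""
    scores = []
    for seed in seeds:
        _, _, buscos, _, truth, track = make_benchmark_dataset(seed, config)
        report = coverage_busco.classify_te_associated(buscos, track, params)
        scores.append(score_detector(report, truth))
    mean_recall = float(np.mean([s.recall for s in scores]))
    mean_fpr = float(np.mean([s.fpr for s in scores]))
    return mean_recall, mean_fpr, scores


# --------------------------------------------------- quantifier scoring

def truth_residual_bases(
    truth: SimulationTruth, busco_id: str
) -> Tuple[int, Optional[str]]:
    """Expected residual hit bases for one TE-associated gene.

    Every intergenic copy of the insert's family shares the insert's
    consensus fragment, so the expected per-base union of hit subject
    intervals outside gene loci is the summed consensus-coordinate overlap
    between the insert fragment and each intergenic copy.  Returns
    (expected bases, family name); (0, None) for genes without inserts.
    """
    inserts = [c for c in truth.placed_copies if c.gene_id == busco_id]
    if not inserts:
        return 0, None
    expected = 0
    fam = inserts[0].family_name
    for ins in inserts:
        for copy in truth.placed_copies:
            if copy.family_name != ins.family_name or copy.gene_id is not None:
                continue
            ov = min(copy.consensus_end, ins.consensus_end) - max(
                copy.consensus_start, ins.consensus_start
            )
            if ov > 0:
                expected += ov
    return expected, fam


@dataclass
class QuantifierScore:
    n_evaluated: int
    dominant_category_accuracy: float
    mean_abs_relative_error: float
    per_busco: List[Dict[str, object]]


def quantifier_benchmark(
    seed: int,
    params: SearchParams = SearchParams(),
    config: Optional[SimulationConfig] = None,
    max_buscos: Optional[int] = None,
) -> QuantifierScore:
    """Quantify every detected truth-positive gene and score the dominant
    repeat category and residual base count against the simulation truth."""
    cfg, genome, buscos, repeats, truth, track = make_benchmark_dataset(
        seed, config
    )
    report = coverage_busco.classify_te_associated(buscos, track)
    categories = {f.family_name: f.category for f in cfg.te_families}
    rows: List[Dict[str, object]] = []
    flagged = [b for b in report.flagged_ids()
               if b in truth.te_associated_genes]
    if max_buscos is not None:
        flagged = flagged[:max_buscos]
    for busco_id in flagged:
        _, counts = te_quantify.quantify_te_associated_busco(
            busco_id, genome, buscos, repeats, params
        )
        expected, fam = truth_residual_bases(truth, busco_id)
        rows.append(
            {
                "busco_id": busco_id,
                "dominant": counts.dominant_category(),
                "expected_category": categories[fam],
                "residual": counts.total_bases,
                "expected_residual": expected,
            }
        )
    n = len(rows)
    acc = float(
        np.mean([r["dominant"] == r["expected_category"] for r in rows])
    ) if n else float("nan")
    rel = float(
        np.mean(
            [
                abs(r["residual"] - r["expected_residual"])
                / max(r["expected_residual"], 1)
                for r in rows
            ]
        )
    ) if n else float("nan")
    return QuantifierScore(n, acc, rel, rows)


# ----------------------------------------------------- contrast scoring

def contrast_benchmark(
    seed: int,
    n_pairs: int = 20,
    params: SearchParams = SearchParams(),
    config: Optional[SimulationConfig] = None,
) -> Tuple[List[float], int]:
    """Inflated-vs-reference query contrast on detected genes.

    The reference query is the gene sequence with its planted insert
    deleted (the ortholog that never gained the fragment); both queries
    run against the same inflated assembly.  Returns (ratios, n_pairs).
    """
    _, genome, buscos, _, truth, track = make_benchmark_dataset(seed, config)
    report = coverage_busco.classify_te_associated(buscos, track)
    flagged = [b for b in report.flagged_ids()
               if b in truth.te_associated_genes][:n_pairs]
    by_id = {b.busco_id: b for b in buscos if b.interval is not None}
    ratios = []
    for busco_id in flagged:
        rec = by_id[busco_id]
        inflated = genome.fetch(rec.interval)
        reference = inflated
        # delete insert spans back-to-front so offsets stay valid
        spans = sorted(
            (
                (c.interval.start - rec.interval.start,
                 c.interval.end - rec.interval.start)
                for c in truth.placed_copies
                if c.gene_id == busco_id
            ),
            reverse=True,
        )
        for s, e in spans:
            reference = reference[:s] + reference[e:]
        result = te_quantify.reference_contrast(
            busco_id, inflated, reference, genome, buscos, [], params
        )
        ratios.append(result.ratio)
    return ratios, len(ratios)


# --------------------------------------------------- validation scoring

def validation_benchmark(
    seed: int,
    n_pairs: int = 75,
    insert_length_range: Tuple[int, int] = (200, 2000),
    max_divergence: float = 0.10,
    ortholog_divergence: float = 0.02,
    gene_length: int = 1500,
    params: AlignParams = AlignParams(),
) -> Tuple[int, int]:
    """Pairwise-alignment validation on constructed inflated/reference pairs.

    Each pair: a reference gene; an inflated ortholog that diverged by
    ``ortholog_divergence`` substitutions and additionally gained a repeat
    fragment (length sampled from ``insert_length_range``, fragment
    divergence up to ``max_divergence``) at a random internal position.
    The flagged region is the insert span.  Returns (n verdict true, n).
    """
    rng = np.random.default_rng(seed)
    n_true = 0
    for i in range(n_pairs):
        gene = random_sequence(rng, gene_length)
        reference, _ = mutate_copy(gene, ortholog_divergence, rng)
        ins_len = int(rng.integers(*insert_length_range, endpoint=True))
        fragment = random_sequence(rng, ins_len)
        fragment, _ = mutate_copy(fragment, rng.uniform(0, max_divergence),
                                  rng)
        pos = int(rng.integers(100, gene_length - 100))
        inflated = gene[:pos] + fragment + gene[pos:]
        verdict = te_quantify.pairwise_validate(
            f"pair{i}", inflated, reference, [(pos, pos + ins_len)], params
        )
        if verdict.gap_overlaps_flagged_region:
            n_true += 1
    return n_true, n_pairs


# --------------------------------------------------- genome-size scoring

def multiplicity_weighted_size(truth: SimulationTruth,
                               genome: GenomeSequenceSet) -> int:
    """Assembly length plus the extra (collapsed-analogue) copies that the
    multiplicity model spreads the read mass over: sum over positions of
    the coverage multiplicity m(p)."""
    counts = truth.family_copy_counts()
    extra = sum(
        (counts[c.family_name] - 1) * len(c.interval)
        for c in truth.placed_copies
    )
    return genome.total_length + extra


def backmap_benchmark(seed: int) -> Dict[str, float]:
    """Genome-size recovery on a simulated track whose repeat family puts
    ~10% of assembly bases at multiplicity 5, at 20x depth."""
    cfg = SimulationConfig(
        genome_length=1_000_000,
        n_contigs=2,
        n_genes=0,
        te_families=(
            FamilySpec("SAT-1_sim", "Satellite", 20_000, 5, ("point", 0.02)),
        ),
        te_associated_fraction=0.0,
        base_depth=20.0,
        seed=seed,
    )
    genome, _, _, truth = simulate_genome(cfg)
    track = simulate_coverage(genome, truth, cfg.base_depth,
                              seed=seed + 100_000)
    hist = genome_size.depth_histogram(track)
    est = genome_size.estimate_size_backmap(hist)
    true_size = multiplicity_weighted_size(truth, genome)
    return {
        "estimate_bp": est.size_bp,
        "true_bp": float(true_size),
        "relative_error": abs(est.size_bp - true_size) / true_size,
        "peak_depth": float(est.peak_depth),
    }


# ----------------------------------------------------- landscape scoring

def landscape_burst_benchmark(
    seed: int,
    burst_divergences: Tuple[float, float] = (0.02, 0.20),
    bin_width: int = 1,
) -> Dict[str, object]:
    """Recover two simulated proliferation bursts from the landscape.

    Two equally abundant families burst at low (recent) and moderate
    (ancient) divergence; the two most abundant divergence bins of the
    landscape should sit within +/-2 bins of the planted burst ages."""
    d1, d2 = burst_divergences
    cfg = SimulationConfig(
        genome_length=600_000,
        n_contigs=2,
        n_genes=0,
        te_families=(
            FamilySpec("LINE-recent_sim", "LINE", 1000, 150,
                       ("normal", d1, 0.01)),
            FamilySpec("DNA-ancient_sim", "DNA", 1000, 150,
                       ("normal", d2, 0.01)),
        ),
        te_associated_fraction=0.0,
        seed=seed,
    )
    genome, _, repeats, _ = simulate_genome(cfg)
    land = divergence_landscape(repeats, genome.total_length, bin_width)
    # one burst per category: the modal divergence bin of each category's
    # abundance profile is that burst's recovered age
    expected = sorted(
        (int(100 * d1 // bin_width), int(100 * d2 // bin_width))
    )
    observed = sorted(
        int(np.argmax(land.category_row(cat))) for cat in ("LINE", "DNA")
    )
    return {
        "expected_bins": expected,
        "observed_bins": observed,
        "max_offset": max(
            abs(o - e) for o, e in zip(observed, expected)
        ),
    }


# ---------------------------------------------- permutation calibration

def type1_error_benchmark(
    seed: int,
    n_replicates: int = 1000,
    n: int = 50,
    n_permutations: int = 499,
    alpha: float = 0.05,
    method: str = "pearson",
) -> Tuple[float, int]:
    """Empirical type-I error of the permutation correlation test under
    an independent standard-normal null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    child_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    for i in range(n_replicates):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        res = association_stats.correlate(
            x, y, method=method, n_permutations=n_permutations,
            seed=int(child_seeds[i]),
        )
        if res.p_perm <= alpha:
            rejections += 1
    return rejections / n_replicates, n_replicates
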