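#!/usr/bin/env python
"""Detect TE-associated genes from the coverage track and score vs truth.

Reads the dataset written by 01_simulate_dataset.py, flags genes with
high-coverage regions (>= 2x the pooled-gene median depth over >= 50 bp),
writes the per-gene table and BED of flagged regions to
results/detection/, and scores recall / false-positive rate against the
planted truth.
"""

import json
import os

from tebusco import io_formats
from tebusco.coverage_busco import classify_te_associated
from tebusco.experiments import score_detector
from tebusco.pipeline import _write_detection
from tebusco.synthetic_data import read_truth

DATASET = os.path.join("results", "dataset")
OUT = os.path.join("results", "detection")


def main() -> None:
    genome = io_formats.read_fasta(os.path.join(DATASET, "genome.fasta"))
    buscos = io_formats.read_busco_full_table(
        os.path.join(DATASET, "busco_full_table.tsv")
    )
    track = io_formats.read_depth(os.path.join(DATASET, "depth.tsv"), genome)
    truth = read_truth(os.path.join(DATASET, "truth.json"))

    report = classify_te_associated(buscos, track)
    os.makedirs(OUT, exist_ok=True)
    _write_detection(report, OUT)
    score = score_detector(report, truth)
    with open(os.path.join(OUT, "detector_score.json"), "w") as fh:
        json.dump(
            {"recall": score.recall, "fpr": score.fpr,
             "n_true_positive": score.n_true_positive,
             "n_false_positive": score.n_false_positive},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")

    print(f"baseline depth: {report.baseline:.1f}x")
    print(f"TE-associated: {report.n_te_associated}/{report.n_denominator} "
          f"genes ({100 * report.fraction:.1f}%)")
    print(f"vs truth: recall {score.recall:.3f}, FPR {score.fpr:.4f} "
          f"({score.n_true_positive} TP, {score.n_false_positive} FP)")


if __name__ == "__main__":
    main()
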