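"""Generator correctness: mutation rates, placement, coverage model,
file-set round trips and determinism."""

import numpy as np
import pytest

from tebusco import io_formats
from tebusco.core import ParameterError, PlacementError
from tebusco.synthetic_data import (
    FamilySpec,
    SimulationConfig,
    mutate_copy,
    random_sequence,
    read_truth,
    simulate_coverage,
    simulate_genome,
    write_dataset,
)


def _mismatch_fraction(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestMutateCopy:
    def test_zero_divergence_is_identity(self, rng):
        seq = random_sequence(rng, 500)
        out, realized = mutate_copy(seq, 0.0, rng)
        assert out == seq
        assert realized == 0.0

    @pytest.mark.parametrize("divergence,lo,hi", [
        # binomial 3-sigma bounds at n=10000 and n=1000
        (0.10, 0.08, 0.12),
        (0.50, 0.45, 0.55),
    ])
    def test_realized_divergence_within_binomial_bounds(
        self, rng, divergence, lo, hi
    ):
        n = 10_000 if divergence == 0.10 else 1_000
        seq = random_sequence(rng, n)
        out, realized = mutate_copy(seq, divergence, rng)
        observed = _mismatch_fraction(seq, out)
        assert lo <= observed <= hi
        assert realized == pytest.approx(observed)

    def test_substitutions_never_keep_the_base(self, rng):
        seq = "ACGT" * 250
        out, realized = mutate_copy(seq, 0.5, rng)
        # realized equals the actual per-site substitution count exactly
        assert realized == _mismatch_fraction(seq, out)
        assert 0.45 <= realized <= 0.55

    @pytest.mark.parametrize("bad", [-0.1, 0.6])
    def test_divergence_out_of_range_raises(self, rng, bad):
        with pytest.raises(ParameterError):
            mutate_copy("ACGT", bad, rng)


class TestSimulateGenome:
    def test_no_families_means_no_repeats_or_associations(self):
        cfg = SimulationConfig(te_families=(), genome_length=500_000,
                               n_genes=50, seed=7)
        _, buscos, repeats, truth = simulate_genome(cfg)
        assert repeats == []
        assert truth.te_associated_genes == {}
        assert len(truth.non_associated_genes) == 50

    def test_feature_counts_and_repeat_bp(self):
        cfg = SimulationConfig(
            genome_length=2_000_000,
            n_genes=200,
            gene_length=("point", 1500),
            te_families=(
                FamilySpec("LINE-1_sim", "LINE", 2000, 300,
                           ("normal", 0.05, 0.02)),
            ),
            te_associated_fraction=0.2,
            seed=3,
        )
        genome, buscos, repeats, truth = simulate_genome(cfg)
        assert len(truth.te_associated_genes) == 40
        assert len(buscos) == 200
        assert all(b.status == "Complete" for b in buscos)
        intergenic = [c for c in truth.placed_copies if c.gene_id is None]
        assert len(intergenic) == 300
        total_repeat_bp = sum(len(c.interval) for c in intergenic)
        assert total_repeat_bp == pytest.approx(300 * 2000, rel=0.10)

    def test_truth_consistent_with_emitted_tables(self, benchmark_dataset):
        cfg, genome, buscos, repeats, truth, _ = benchmark_dataset
        # conservation: placed copy lengths = total .out bases
        assert sum(len(c.interval) for c in truth.placed_copies) == \
            sum(len(h.interval) for h in repeats)
        # every insert is inside (or abuts) its gene's emitted interval
        by_id = {b.busco_id: b for b in buscos}
        for gid, inserts in truth.te_associated_genes.items():
            g_iv = by_id[gid].interval
            for iv in inserts:
                assert iv.contig == g_iv.contig
                assert iv.start >= g_iv.start - cfg.adjacency_window
                assert iv.end <= g_iv.end + cfg.adjacency_window
        # associated and non-associated gene sets are disjoint
        assert not set(truth.te_associated_genes) & \
            set(truth.non_associated_genes)

    def test_placed_copies_do_not_overlap(self, benchmark_dataset):
        _, _, _, _, truth, _ = benchmark_dataset
        by_contig = {}
        for c in truth.placed_copies:
            by_contig.setdefault(c.interval.contig, []).append(
                (c.interval.start, c.interval.end)
            )
        for ivs in by_contig.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_planted_sequence_matches_consensus_at_divergence(
        self, benchmark_dataset
    ):
        _, genome, _, _, truth, _ = benchmark_dataset
        copy = truth.placed_copies[0]
        placed = genome.fetch(copy.interval)
        consensus = truth.family_consensus[copy.family_name][
            copy.consensus_start : copy.consensus_end
        ]
        assert _mismatch_fraction(consensus, placed) == pytest.approx(
            copy.realized_divergence
        )

    def test_determinism(self):
        cfg = SimulationConfig(genome_length=300_000, n_genes=20, seed=11)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2] == b[2]

    def test_infeasible_placement_raises(self):
        cfg = SimulationConfig(
            genome_length=100_000, n_genes=200,
            gene_length=("point", 1500), seed=1,
        )
        with pytest.raises(PlacementError):
            simulate_genome(cfg)


class TestSimulateCoverage:
    def test_zero_depth_gives_all_zero_track(self):
        cfg = SimulationConfig(genome_length=50_000, n_contigs=1,
                               n_genes=5, te_families=(), seed=2)
        genome, _, _, truth = simulate_genome(cfg)
        track = simulate_coverage(genome, truth, 0.0, seed=3)
        assert track.total_mapped_bases == 0

    def test_nonrepeat_mean_depth_matches_poisson(self):
        cfg = SimulationConfig(genome_length=100_000, n_contigs=1,
                               n_genes=0, te_families=(), seed=5)
        genome, _, _, truth = simulate_genome(cfg)
        track = simulate_coverage(genome, truth, 20.0, seed=6)
        mean = track.depth("contig_1").mean()
        assert 19.5 <= mean <= 20.5

    def test_planted_insert_depth_dominates_gene_body(
        self, benchmark_dataset
    ):
        _, genome, buscos, _, truth, track = benchmark_dataset
        by_id = {b.busco_id: b for b in buscos}
        genome_median = np.median(track.all_positions())
        for gid, inserts in list(truth.te_associated_genes.items())[:10]:
            iv = inserts[0]
            insert_mean = track.slice(iv).mean()
            # multiplicity >= copy number 50 at 10x vs haploid baseline
            assert insert_mean >= 5 * genome_median
            assert insert_mean >= 2 * genome_median  # planted-signal floor


class TestWriteDataset:
    def test_round_trip_and_manifest(self, tmp_path):
        cfg = SimulationConfig(genome_length=200_000, n_contigs=2,
                               n_genes=20, seed=9)
        genome, buscos, repeats, truth = simulate_genome(cfg)
        track = simulate_coverage(genome, truth, cfg.base_depth, seed=10)
        paths = write_dataset(str(tmp_path / "ds"), genome, buscos, repeats,
                              truth, track, cfg)
        g2 = io_formats.read_fasta(paths["genome"])
        assert g2 == genome
        assert io_formats.read_busco_full_table(paths["busco_table"]) == buscos
        assert io_formats.read_repeatmasker_out(paths["repeats"]) == repeats
        assert io_formats.read_depth(paths["depth"], genome) == track
        truth2 = read_truth(paths["truth"])
        assert truth2.placed_copies == truth.placed_copies
        assert truth2.te_associated_genes == truth.te_associated_genes
        manifest = (tmp_path / "ds" / "manifest.tsv").read_text()
        assert f"seed\t{cfg.seed}" in manifest
        assert cfg.config_hash() in manifest

    def test_out_divergence_column_matches_truth(self, tmp_path):
        cfg = SimulationConfig(genome_length=200_000, n_contigs=1,
                               n_genes=10, seed=4)
        genome, buscos, repeats, truth = simulate_genome(cfg)
        track = simulate_coverage(genome, truth, cfg.base_depth, seed=5)
        paths = write_dataset(str(tmp_path / "ds"), genome, buscos, repeats,
                              truth, track, cfg)
        back = io_formats.read_repeatmasker_out(paths["repeats"])
        for hit, copy in zip(back, truth.placed_copies):
            assert hit.divergence == pytest.approx(
                round(copy.realized_divergence * 100, 1)
            )

    def test_config_hash_changes_iff_config_changes(self):
        a = SimulationConfig(seed=1)
        b = SimulationConfig(seed=1)
        c = SimulationConfig(seed=2)
        assert a.config_hash() == b.config_hash()
        assert a.config_hash() != c.config_hash()

    def test_byte_identical_file_set_for_same_seed(self, tmp_path):
        for d in ("run1", "run2"):
            cfg = SimulationConfig(genome_length=300_000, n_contigs=1,
                                   n_genes=10, seed=13)
            genome, buscos, repeats, truth = simulate_genome(cfg)
            track = simulate_coverage(genome, truth, cfg.base_depth, seed=14)
            write_dataset(str(tmp_path / d), genome, buscos, repeats, truth,
                          track, cfg)
        for name in ("genome.fasta", "busco_full_table.tsv", "repeats.out",
                     "depth.tsv", "truth.json", "manifest.tsv"):
            assert (tmp_path / "run1" / name).read_bytes() == \
                (tmp_path / "run2" / name).read_bytes()
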