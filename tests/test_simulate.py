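"""The synthetic genome / strain / read generator."""

import io

import numpy as np
import pytest

from _oracles import revcomp as oracle_revcomp
from lintopo import Genome, write_fastq
from lintopo.simulate import (
    Circularize,
    DropReplicon,
    StrainSpec,
    derive_strain,
    generate_replicon,
    simulate_reads,
)


class TestGenerateReplicon:
    def test_gc_fraction_matches_target(self):
        rep = generate_replicon("r", 10_000, gc=0.70, seed=1)
        gc = (rep.sequence.count("G") + rep.sequence.count("C")) / rep.length
        assert abs(gc - 0.70) <= 0.02

    @pytest.mark.parametrize("tir", [348, 400])
    def test_planted_tir_is_exact_reverse_complement(self, tir):
        rep = generate_replicon("r", 5_000, tir_length=tir, seed=2)
        assert oracle_revcomp(rep.sequence[:tir]) == rep.sequence[-tir:]

    def test_zero_tir_means_no_enforced_symmetry(self):
        rep = generate_replicon("r", 5_000, tir_length=0, seed=3)
        # astronomically unlikely to hold by chance on 100 bp
        assert oracle_revcomp(rep.sequence[:100]) != rep.sequence[-100:]

    def test_deterministic_for_seed(self):
        a = generate_replicon("r", 2_000, seed=4)
        b = generate_replicon("r", 2_000, seed=4)
        c = generate_replicon("r", 2_000, seed=5)
        assert a.sequence == b.sequence
        assert a.sequence != c.sequence

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_replicon("r", 100, gc=1.5)
        with pytest.raises(ValueError):
            generate_replicon("r", 100, tir_length=60)


class TestDeriveStrain:
    def test_circularize_published_chromosome_arithmetic(self):
        # a 6,748,580 bp chromosome losing its first 98,993 and last
        # 115,914 bp circularizes into a 6,533,673 bp molecule
        n, dl, dr = 6_748_580, 98_993, 115_914
        rep = generate_replicon("chr", n, seed=6)
        genome = Genome([rep], "chr")
        mutant = derive_strain(genome, StrainSpec([Circularize("chr", dl, dr)]))
        out = mutant["chr"]
        assert out.topology == "circular"
        assert out.length == 6_533_673 == n - dl - dr
        assert out.sequence[0] == rep.sequence[dl]  # starts at original dl+1
        assert out.sequence[-1] == rep.sequence[n - dr - 1]  # ends at n-dr

    def test_drop_leaves_survivors_byte_identical(self, small_genome):
        mutant = derive_strain(small_genome, StrainSpec([DropReplicon("pA")]))
        assert mutant.names == ["chr"]
        assert mutant["chr"].sequence == small_genome["chr"].sequence

    def test_pure_circularization(self, small_genome):
        mutant = derive_strain(small_genome, StrainSpec([Circularize("chr", 0, 0)]))
        out = mutant["chr"]
        assert out.topology == "circular"
        assert out.sequence == small_genome["chr"].sequence

    def test_event_on_missing_replicon(self, small_genome):
        with pytest.raises(ValueError, match="missing replicon"):
            derive_strain(small_genome, StrainSpec([DropReplicon("nope")]))

    def test_oversized_deletions_rejected(self, small_genome):
        with pytest.raises(ValueError, match="deletions"):
            derive_strain(
                small_genome, StrainSpec([Circularize("pA", 3000, 1500)])
            )


class TestSimulateReads:
    def test_zero_depth_gives_no_reads(self, small_genome):
        assert simulate_reads(small_genome, mean_depth=0, seed=1) == []

    def test_pair_count_matches_expectation(self):
        genome = Genome([generate_replicon("chr", 100_000, seed=8)], "chr")
        reads = simulate_reads(genome, mean_depth=50, read_len=250,
                               insert_mean=500, seed=9)
        pairs = len(reads) // 2
        # expectation 10,000; Poisson sd = 100 -> 5 sd band
        assert abs(pairs - 10_000) <= 500

    def test_errorfree_reads_are_verbatim_substrings(self, small_genome,
                                                     small_errorfree_reads):
        for read in small_errorfree_reads[:2000]:
            source = small_genome[read.truth.source_replicon].sequence
            probe = read.sequence if read.truth.strand == "+" else oracle_revcomp(read.sequence)
            assert probe in source

    def test_truth_records_reconstruct_alignment(self, small_genome,
                                                 small_errorfree_reads):
        for read in small_errorfree_reads[:2000]:
            t = read.truth
            source = small_genome[t.source_replicon].sequence
            window = source[t.source_start - 1 : t.source_start - 1 + len(read.sequence)]
            expected = window if t.strand == "+" else oracle_revcomp(window)
            assert read.sequence == expected

    def test_circular_reads_wrap_origin(self):
        rep = generate_replicon("c", 3_000, seed=10, topology="circular")
        genome = Genome([rep], "c")
        reads = simulate_reads(genome, mean_depth=30, read_len=150, sub_error=0.0, seed=11)
        doubled = rep.sequence * 2
        wrapped = 0
        for read in reads:
            t = read.truth
            probe = read.sequence if t.strand == "+" else oracle_revcomp(read.sequence)
            assert doubled[t.source_start - 1 : t.source_start - 1 + 150] == probe
            if t.source_start + 150 - 1 > rep.length:
                wrapped += 1
        assert wrapped > 0  # origin-crossing reads exist

    def test_terminal_depth_depressed_on_linear_replicons(self, small_genome):
        reads = simulate_reads(small_genome, mean_depth=40, read_len=150, seed=12)
        n = small_genome["chr"].length
        diff = np.zeros(n + 1)
        for read in reads:
            t = read.truth
            if t.source_replicon != "chr":
                continue
            diff[t.source_start - 1] += 1
            diff[min(n, t.source_start - 1 + 150)] -= 1
        depth = np.cumsum(diff[:-1])
        terminal = np.concatenate([depth[:150], depth[-150:]]).mean()
        interior = depth[150:-150].mean()
        assert terminal < interior

    def test_copy_number_scales_depth(self, small_genome):
        reads = simulate_reads(small_genome, mean_depth=20, seed=13,
                               copy_numbers={"pA": 2.0})
        per_rep = {"chr": 0, "pA": 0}
        for read in reads:
            per_rep[read.truth.source_replicon] += 1
        chr_depth = per_rep["chr"] * 150 / small_genome["chr"].length
        pA_depth = per_rep["pA"] * 150 / small_genome["pA"].length
        assert pA_depth / chr_depth == pytest.approx(2.0, rel=0.15)

    def test_error_rate_and_error_counts(self, small_genome):
        reads = simulate_reads(small_genome, mean_depth=5, sub_error=0.01, seed=14)
        total_errors = sum(r.truth.errors_introduced for r in reads)
        total_bases = sum(len(r.sequence) for r in reads)
        assert total_errors / total_bases == pytest.approx(0.01, rel=0.1)

    def test_identical_seed_gives_byte_identical_fastq(self, small_genome):
        outputs = []
        for _ in range(2):
            reads = simulate_reads(small_genome, mean_depth=3, seed=15)
            buf = io.StringIO()
            write_fastq(reads, buf)
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_invalid_rates_rejected(self, small_genome):
        with pytest.raises(ValueError):
            simulate_reads(small_genome, sub_error=1.5)
        with pytest.raises(ValueError):
            simulate_reads(small_genome, read_len=600, insert_mean=500)
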