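import numpy as np
import pytest

from plastidkit.fixtures import ReadSimSpec, simulate_reads
from plastidkit.readmap import (
    CoverageProfile,
    MappingParameters,
    ReadAlignment,
    ReferenceIndex,
    STRICT_PARAMETERS,
    accept_alignment,
    align_read,
    best_alignments,
    compute_coverage,
    dual_stringency_report,
    remap_circular_junction,
    screen_low_coverage,
)
from plastidkit.seqio import GenomeRegion, NucleotideSequence, revcomp

from .oracles import local_alignment_best_score


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate(seq, positions):
    comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
    chars = list(seq)
    for p in positions:
        chars[p] = comp[chars[p]]
    return "".join(chars)


@pytest.fixture(scope="module")
def reference():
    return NucleotideSequence("ref", _random_seq(4000, 42))


class TestAlignRead:
    def test_exact_substring(self, reference):
        read = NucleotideSequence("r", reference.residues[100:179])
        aln = align_read(read, reference)
        assert aln.identity == 1.0
        assert aln.aligned_read_fraction == 1.0
        assert (aln.ref_interval.start, aln.ref_interval.end) == (100, 179)
        assert aln.strand == "+"

    def test_reverse_strand(self, reference):
        read = NucleotideSequence("r", revcomp(reference.residues[200:279]))
        aln = align_read(read, reference)
        assert aln.strand == "-"
        assert aln.ref_interval.start == 200

    def test_three_substitutions_identity(self, reference):
        raw = reference.residues[500:580]
        read = NucleotideSequence("r", _mutate(raw, [10, 40, 70]))
        aln = align_read(read, reference)
        assert aln.identity == pytest.approx(77 / 80)
        assert accept_alignment(aln, MappingParameters())

    def test_nine_substitutions_rejected(self):
        # toy pair small enough for the exhaustive (un-seeded) path: nine
        # substitutions leave no exact seed, but the DP still aligns it
        toy = NucleotideSequence("toy", _random_seq(1000, 43))
        raw = toy.residues[500:580]
        read = NucleotideSequence("r", _mutate(raw, list(range(5, 77, 8))))
        aln = align_read(read, toy)
        assert aln.identity == pytest.approx(71 / 80)
        assert not accept_alignment(aln, MappingParameters())

    def test_unalignable_read_absent(self, reference):
        read = NucleotideSequence("r", "AC" * 40)
        aln = align_read(read, reference)
        if aln is not None:  # a chance local hit must at least be poor
            assert aln.identity < 0.9 or aln.aligned_read_fraction < 0.8

    def test_short_read_rejected(self, reference):
        with pytest.raises(ValueError):
            align_read(NucleotideSequence("r", "ACGTACGTACGT"), reference)

    def test_agrees_with_dp_oracle_grid(self):
        # reads <= 30 nt vs references <= 200 nt, enumerable by brute force
        rng = np.random.default_rng(7)
        params = MappingParameters()
        for trial in range(30):
            ref = _random_seq(int(rng.integers(60, 200)), 1000 + trial)
            start = int(rng.integers(0, len(ref) - 30))
            if trial % 3 == 0:
                read_res = _random_seq(25, 2000 + trial)
            else:
                read_res = ref[start : start + 30]
                n_mut = int(rng.integers(0, 4))
                muts = rng.choice(30, size=n_mut, replace=False)
                read_res = _mutate(read_res, [int(m) for m in muts])
                if trial % 2:
                    read_res = revcomp(read_res)
            oracle = local_alignment_best_score(ref, read_res)
            aln = align_read(
                NucleotideSequence("r", read_res), NucleotideSequence("ref", ref), params
            )
            got = aln.score if aln is not None else 0.0
            assert got == oracle, f"trial {trial}: {got} != oracle {oracle}"

    def test_multimapping_read_hits_both_ir_copies(self, small_plastome):
        genome, structure, _, _ = small_plastome
        ira = structure.ira[0]
        read = NucleotideSequence("r", genome.residues[ira.start + 50 : ira.start + 129])
        hits = best_alignments(read, genome)
        assert len(hits) == 2
        starts = sorted(h.ref_interval.start for h in hits)
        assert starts[0] == ira.start + 50
        assert {h.strand for h in hits} == {"+", "-"}


class TestAcceptance:
    def _aln(self, fraction, identity):
        return ReadAlignment(
            read_id="r", ref_interval=GenomeRegion("g", 0, 10), strand="+",
            matches=8, mismatches=0, insertions=0, deletions=0,
            aligned_read_fraction=fraction, identity=identity, score=8.0,
        )

    def test_perfect(self):
        assert accept_alignment(self._aln(1.0, 1.0), MappingParameters())

    def test_below_length_fraction(self):
        assert not accept_alignment(self._aln(0.79, 0.95), MappingParameters())

    def test_inclusive_boundary(self):
        assert accept_alignment(self._aln(0.80, 0.90), MappingParameters())

    def test_monotonicity_in_thresholds(self, reference):
        reads = simulate_reads(reference, ReadSimSpec(depth=3, substitution_rate=0.05, seed=3))
        index = ReferenceIndex(reference)
        loose = compute_coverage(reads, index, MappingParameters())
        strict = compute_coverage(reads, index, STRICT_PARAMETERS)
        assert strict.mapped_read_count <= loose.mapped_read_count


class TestCoverage:
    def test_zero_reads(self, reference):
        profile = compute_coverage([], reference)
        assert profile.mean_depth == 0
        assert profile.depth.sum() == 0

    def test_conservation(self, reference):
        reads = simulate_reads(reference, ReadSimSpec(depth=2, seed=5))
        index = ReferenceIndex(reference)
        params = MappingParameters()
        total_aligned = 0
        for read in reads:
            for h in best_alignments(read, index, params):
                if accept_alignment(h, params):
                    total_aligned += h.ref_interval.end - h.ref_interval.start
        profile = compute_coverage(reads, index, params)
        assert int(profile.depth.sum()) == total_aligned

    def test_mean_depth_recovers_simulated_depth(self):
        # binomial sampling oracle: mean within 3 SE of the simulated depth
        depth, n, read_len = 60.0, 6000, 79
        ref = NucleotideSequence("ref", _random_seq(n, 77))
        reads = simulate_reads(ref, ReadSimSpec(depth=depth, substitution_rate=0.005, seed=6))
        profile = compute_coverage(reads, ref)
        se = np.sqrt(depth * read_len / n)
        # circular reads spanning the origin clip on the linear reference
        edge_loss = depth * read_len / n
        assert abs(profile.mean_depth - depth) <= 3 * se + edge_loss

    def test_error_free_reads_all_accepted_strict(self, reference):
        reads = simulate_reads(reference, ReadSimSpec(depth=1, seed=8))
        # drop reads spanning the circular origin: they clip on a linear ref
        reads = [r for r in reads if r.residues in reference.residues
                 or revcomp(r.residues) in reference.residues]
        profile = compute_coverage(reads, reference, STRICT_PARAMETERS)
        assert profile.mapped_read_count == len(reads)


class TestLowCoverageScreen:
    def _profile(self, depth):
        arr = np.asarray(depth)
        return CoverageProfile(depth=arr, mapped_read_count=0, total_read_count=0)

    def test_uniform_high(self):
        assert screen_low_coverage(self._profile([100] * 50)) == []

    def test_single_base_below(self):
        regions = screen_low_coverage(self._profile([100] * 10 + [39] + [100] * 10))
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (10, 11)
        assert regions[0].min_depth_in_interval == 39

    def test_boundary_is_strict(self):
        assert screen_low_coverage(self._profile([40] * 20)) == []

    def test_planted_zero_window(self):
        depth = [100] * 100 + [0] * 50 + [100] * 100
        regions = screen_low_coverage(self._profile(depth))
        assert len(regions) == 1
        assert len(regions[0].interval) == 50


class TestCircularJunction:
    def test_junction_segment_length(self, small_plastome):
        genome, structure, _, _ = small_plastome
        profile = remap_circular_junction([], genome, structure, window=800)
        assert len(profile.depth) == 1600

    def test_zero_reads_zero_profile(self, small_plastome):
        genome, structure, _, _ = small_plastome
        profile = remap_circular_junction([], genome, structure, window=500)
        assert profile.depth.sum() == 0

    def test_window_truncated_with_warning(self, small_plastome):
        genome, structure, _, _ = small_plastome
        with pytest.warns(UserWarning, match="truncated"):
            profile = remap_circular_junction([], genome, structure, window=10_000)
        assert len(profile.depth) == 2 * min(structure.ir_length, structure.lsc_length)

    def test_resolves_terminal_coverage_drop(self, small_plastome):
        genome, structure, _, _ = small_plastome
        reads = simulate_reads(genome, ReadSimSpec(depth=50, seed=9))
        reads = reads[:2000]  # desk scale: enough to cover the junction
        linear = compute_coverage(reads, genome)
        junction = remap_circular_junction(reads, genome, structure, window=400)
        # linear mapping always under-covers the last bases of IRb
        assert linear.depth[-1] < junction.depth[399]


class TestDualStringency:
    def test_error_free_identical(self, reference):
        reads = simulate_reads(reference, ReadSimSpec(depth=1.5, seed=10))
        reads = [r for r in reads if r.residues in reference.residues
                 or revcomp(r.residues) in reference.residues]
        report = dual_stringency_report(reads, reference)
        assert np.array_equal(report.default_profile.depth, report.strict_profile.depth)
        assert report.mean_delta == 0

    def test_errors_reduce_strict_mean(self, reference):
        reads = simulate_reads(reference, ReadSimSpec(depth=3, substitution_rate=0.01, seed=11))
        report = dual_stringency_report(reads, reference)
        assert report.strict_profile.mean_depth <= report.default_profile.mean_depth
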