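from dataclasses import replace

import numpy as np
import pytest

from plastidkit.compare import (
    ComparisonError,
    analyze_ir_boundaries,
    coverage_consistency_check,
    detect_foreign_insert,
    pairwise_compare,
    region_metrics,
    scan_pseudogenes,
)
from plastidkit.fixtures import PlastomeSpec, ReadSimSpec, generate_plastome, simulate_reads
from plastidkit.readmap import CoverageProfile, compute_coverage
from plastidkit.seqio import (
    Feature,
    FeatureTable,
    GenomeRegion,
    NucleotideSequence,
    revcomp,
)

COMP = {"A": "C", "C": "G", "G": "T", "T": "A"}


class TestRegionMetrics:
    def test_length_identity(self, small_plastome):
        genome, structure, _, _ = small_plastome
        m = region_metrics(genome, structure)
        assert m.genome_length == m.lsc_length + m.ssc_length + 2 * m.ir_length
        assert m.genome_length == len(genome)

    def test_printed_row_arithmetic(self):
        # published example row: the four region sizes must reconstruct the total
        assert 84_541 + 18_916 + 2 * 24_942 == 153_341

    def test_coding_fractions(self, small_plastome):
        genome, structure, _, _ = small_plastome
        features = FeatureTable(
            genome.id,
            [
                Feature("a", "CDS", (GenomeRegion(genome.id, 100, 1100),), "+", 1),
                Feature("b", "tRNA", (GenomeRegion(genome.id, 2000, 2075),), "+", 1),
                # overlapping CDS: overlap must count once
                Feature("c", "CDS", (GenomeRegion(genome.id, 600, 1600),), "+", 1),
            ],
        )
        m = region_metrics(genome, structure, features)
        n = len(genome)
        assert m.percent_protein_coding == pytest.approx(100 * 1500 / n, abs=0.01)
        assert m.percent_rna_coding == pytest.approx(100 * 75 / n, abs=0.01)
        assert m.percent_coding == pytest.approx(100 * 1575 / n, abs=0.01)

    def test_regional_gc_targets(self):
        genome, structure, _, _ = generate_plastome(
            PlastomeSpec(lsc_length=30_000, ssc_length=8_000, ir_length=9_000,
                         gc_by_region={"lsc": 0.34, "ssc": 0.29, "ir": 0.43}, seed=3)
        )
        m = region_metrics(genome, structure)
        assert m.ssc_gc_percent == pytest.approx(29.0, abs=1.5)
        assert m.ir_gc_percent == pytest.approx(43.0, abs=1.5)


class TestPseudogenes:
    def _table(self, genome_id, length, strand="+", codon_start=1):
        return FeatureTable(
            genome_id,
            [Feature("gene1", "CDS", (GenomeRegion(genome_id, 0, length),), strand, codon_start)],
        )

    def test_terminal_stop_not_internal(self):
        seq = NucleotideSequence("x", "ATGAAATAA" + "G" * 30)
        calls = scan_pseudogenes(seq, self._table("x", 9))
        assert calls == []

    def test_one_internal_stop(self):
        seq = NucleotideSequence("x", "ATGTAAAAATAA" + "G" * 30)
        calls = scan_pseudogenes(seq, self._table("x", 12))
        assert len(calls) == 1
        assert calls[0].internal_stop_count == 1
        assert calls[0].stop_codon_positions == (2,)

    def test_four_planted_stops(self):
        coding = "ATG" + "TAA" + "AAA" + "TAG" + "CCC" + "TGA" + "GGG" + "TAA" + "AAA" + "TAA"
        seq = NucleotideSequence("x", coding + "G" * 30)
        calls = scan_pseudogenes(seq, self._table("x", len(coding)))
        assert calls[0].internal_stop_count == 4

    def test_minus_strand(self):
        coding = "ATGTAAAAATAA"
        seq = NucleotideSequence("x", "G" * 10 + revcomp(coding) + "G" * 10)
        table = FeatureTable(
            "x", [Feature("m", "CDS", (GenomeRegion("x", 10, 22, "-"),), "-", 1)]
        )
        calls = scan_pseudogenes(seq, table)
        assert len(calls) == 1
        assert calls[0].stop_codon_positions == (2,)

    def test_frame_anomaly_flagged(self):
        seq = NucleotideSequence("x", "ATGTAAAAATAAG" + "G" * 30)
        calls = scan_pseudogenes(seq, self._table("x", 13))
        assert calls[0].frame_anomaly is True

    def test_codon_start_respected(self):
        seq = NucleotideSequence("x", "GATGTAAAAATAA" + "G" * 30)
        calls = scan_pseudogenes(seq, self._table("x", 13, codon_start=2))
        assert len(calls) == 1
        assert calls[0].stop_codon_positions == (2,)


class TestIRBoundaries:
    def test_partial_copy(self):
        genome, structure, features, registry = generate_plastome(
            PlastomeSpec(lsc_length=20_000, ssc_length=6_000, ir_length=7_000,
                         seed=41, planted_boundary_gene=("partial", 5_400))
        )
        report = analyze_ir_boundaries(genome, structure, features)
        assert report.boundary_gene_status == "partial pseudogene (1200 nt)"
        assert report.ir_copy_length == registry.boundary_gene.ir_copy_length

    def test_full_copy_and_expansion(self):
        genome, structure, features, _ = generate_plastome(
            PlastomeSpec(lsc_length=20_000, ssc_length=6_000, ir_length=7_000,
                         seed=42, planted_boundary_gene=("full", 5_400))
        )
        report = analyze_ir_boundaries(
            genome, structure, features, comparator_ir_length=5_000
        )
        assert report.boundary_gene_status == "full copy"
        assert report.ir_expansion_flag is True
        assert report.expansion_length == 2_000

    def test_absent_gene(self, small_plastome):
        genome, structure, _, _ = small_plastome
        report = analyze_ir_boundaries(
            genome, structure, FeatureTable(genome.id, [])
        )
        assert report.boundary_gene_status == "absent"
        assert all(not genes for genes in report.junction_genes.values())


@pytest.fixture(scope="module")
def pair():
    genome, _, _, _ = generate_plastome(
        PlastomeSpec(lsc_length=50_000, ssc_length=12_000, ir_length=15_000, seed=51)
    )
    res = list(genome.residues)
    snp_positions = [4_000, 11_000, 22_000, 33_000, 44_000]
    for p in snp_positions:
        res[p] = COMP[res[p]]
    b = "".join(res)
    b = b[:40_000] + b[40_007:]  # 7 nt deletion
    b = b[:30_000] + b[30_003:]  # 3 nt deletion
    return genome, replace(genome, residues=b)


@pytest.fixture(scope="module")
def insert_fixture():
    base = dict(lsc_length=30_000, ssc_length=8_000, ir_length=9_000, seed=31)
    host, _, _, _ = generate_plastome(PlastomeSpec(**base))
    genome, structure, _, registry = generate_plastome(
        PlastomeSpec(**base, planted_insert=("mito", 4_800, "LSC"))
    )
    mito_ref = NucleotideSequence("mito_ref", registry.insert.donor_residues)
    return host, genome, structure, registry, mito_ref


class TestPairwiseCompare:
    def test_self_comparison(self, small_plastome):
        genome, _, _, _ = small_plastome
        result = pairwise_compare(genome, genome)
        assert result.snp_count == 0
        assert result.indel_event_count == 0
        assert result.percent_identity == 100.0

    def test_planted_variants_recovered(self, pair):
        a, b = pair
        result = pairwise_compare(a, b)
        assert result.snp_count == 5
        assert result.indel_event_count == 2
        assert result.indel_bases == 10
        snps = [v for v in result.variants if v.kind == "snp"]
        assert sorted(v.pos_a for v in snps) == [4_000, 11_000, 22_000, 33_000, 44_000]

    def test_symmetric_counts(self, pair):
        a, b = pair
        fwd = pairwise_compare(a, b)
        rev = pairwise_compare(b, a)
        assert fwd.snp_count == rev.snp_count
        assert fwd.indel_event_count == rev.indel_event_count

    def test_flipped_lsc_normalized(self, pair):
        a, _ = pair
        structure = None
        from plastidkit.quadripartite import detect_inverted_repeats

        structure = detect_inverted_repeats(a)
        parts = {n: structure.region_sequence(a, n) for n in ("lsc", "ira", "ssc", "irb")}
        flipped = replace(
            a, residues=revcomp(parts["lsc"]) + parts["ira"] + parts["ssc"] + parts["irb"]
        )
        result = pairwise_compare(a, flipped)
        assert result.snp_count == 0
        assert result.applied_flips.lsc_flipped is True

    def test_unrelated_genomes_raise(self):
        rng = np.random.default_rng(5)
        a, _, _, _ = generate_plastome(
            PlastomeSpec(lsc_length=8_000, ssc_length=2_000, ir_length=2_500, seed=52)
        )
        b, _, _, _ = generate_plastome(
            PlastomeSpec(lsc_length=8_000, ssc_length=2_000, ir_length=2_500, seed=53)
        )
        with pytest.raises(ComparisonError):
            pairwise_compare(a, b, normalize=False)


class TestForeignInsert:
    def test_exact_boundary_recovery(self, insert_fixture):
        host, genome, _, registry, mito_ref = insert_fixture
        calls = detect_foreign_insert(genome, [host], [mito_ref])
        assert len(calls) == 1
        call = calls[0]
        assert call.classification == "mito-like"
        assert call.interval.start == registry.insert.start
        assert call.interval.end == registry.insert.end

    def test_clean_genome_no_calls(self, insert_fixture):
        host, _, _, _, mito_ref = insert_fixture
        assert detect_foreign_insert(host, [host], [mito_ref]) == []

    def test_below_min_insert_threshold(self):
        base = dict(lsc_length=20_000, ssc_length=5_000, ir_length=6_000, seed=32)
        host, _, _, _ = generate_plastome(PlastomeSpec(**base))
        genome, _, _, registry = generate_plastome(
            PlastomeSpec(**base, planted_insert=("mito", 600, "LSC"))
        )
        mito_ref = NucleotideSequence("m", registry.insert.donor_residues)
        assert detect_foreign_insert(genome, [host], [mito_ref], min_insert=1000) == []

    def test_empty_refs_raise(self, insert_fixture):
        _, genome, _, _, mito_ref = insert_fixture
        with pytest.raises(ValueError):
            detect_foreign_insert(genome, [], [mito_ref])


class TestCoverageConsistency:
    def _call(self, start, end):
        from plastidkit.compare import ForeignInsertCall

        return ForeignInsertCall(
            interval=GenomeRegion("g", start, end, label="foreign_insert"),
            classification="mito-like", mito_identity=1.0, plastid_identity=0.0,
            flanking_genes=("", ""),
        )

    def _profile(self, depth):
        return CoverageProfile(
            depth=np.asarray(depth, dtype=np.int64), mapped_read_count=0, total_read_count=0
        )

    def test_uniform_consistent(self):
        profile = self._profile([100] * 20_000)
        verdict = coverage_consistency_check(self._call(8_000, 12_000), profile)
        assert verdict.verdict == "consistent"
        assert verdict.ratio == pytest.approx(1.0)

    def test_five_fold_inconsistent(self):
        depth = [100] * 8_000 + [500] * 4_000 + [100] * 8_000
        verdict = coverage_consistency_check(self._call(8_000, 12_000), self._profile(depth))
        assert verdict.verdict == "inconsistent"
        assert verdict.ratio == pytest.approx(5.0)

    def test_zero_coverage_insert(self):
        depth = [100] * 8_000 + [0] * 4_000 + [100] * 8_000
        verdict = coverage_consistency_check(self._call(8_000, 12_000), self._profile(depth))
        assert verdict.verdict == "inconsistent"
        assert verdict.ratio == 0.0

    def test_simulated_uniform_reads_consistent(self):
        base = dict(lsc_length=12_000, ssc_length=3_000, ir_length=4_000, seed=33)
        genome, _, _, registry = generate_plastome(
            PlastomeSpec(**base, planted_insert=("mito", 1_500, "LSC"))
        )
        reads = simulate_reads(genome, ReadSimSpec(depth=25, seed=33))
        profile = compute_coverage(reads, genome)
        call = self._call(registry.insert.start, registry.insert.end)
        verdict = coverage_consistency_check(call, profile, flank=2_000)
        assert verdict.verdict == "consistent"
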