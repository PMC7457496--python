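"""Comparative analyses over finished plastomes: per-region metrics,
pseudogene scanning, IR-boundary/expansion reporting, anchor-based pairwise
variant counting and mitochondrion-derived insert detection."""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner

from ._seeds import kmer_index, kmer_set
from .quadripartite import (
    QuadripartiteStructure,
    detect_inverted_repeats,
    normalize_orientation,
)
from .readmap import CoverageProfile
from .seqio import (
    Feature,
    FeatureTable,
    GenomeRegion,
    NucleotideSequence,
    gc_content,
    revcomp,
    translate_cds,
)


class ComparisonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Region metrics

@dataclass
class RegionMetrics:
    genome_length: int
    genome_gc_percent: float
    lsc_length: int
    lsc_gc_percent: float
    ssc_length: int
    ssc_gc_percent: float
    ir_length: int
    ir_gc_percent: float
    percent_coding: float | None = None
    percent_protein_coding: float | None = None
    percent_rna_coding: float | None = None


def region_metrics(
    genome: NucleotideSequence,
    structure: QuadripartiteStructure,
    features: FeatureTable | None = None,
) -> RegionMetrics:
    """Length and GC per region, plus coding fractions when annotations are
    available. Overlapping feature intervals count once."""
    pct = lambda x: round(100 * x, 2)
    metrics = RegionMetrics(
        genome_length=len(genome),
        genome_gc_percent=pct(gc_content(genome)),
        lsc_length=structure.lsc_length,
        lsc_gc_percent=pct(gc_content(structure.region_sequence(genome, "lsc"))),
        ssc_length=structure.ssc_length,
        ssc_gc_percent=pct(gc_content(structure.region_sequence(genome, "ssc"))),
        ir_length=structure.ir_length,
        ir_gc_percent=pct(gc_content(structure.region_sequence(genome, "ira"))),
    )
    if features is not None:
        n = len(genome)
        cds_mask = np.zeros(n, dtype=bool)
        rna_mask = np.zeros(n, dtype=bool)
        for f in features.features:
            mask = cds_mask if f.kind == "CDS" else (
                rna_mask if f.kind in ("tRNA", "rRNA") else None
            )
            if mask is None:
                continue
            for r in f.intervals:
                mask[r.start : r.end] = True
        metrics.percent_protein_coding = pct(cds_mask.sum() / n)
        metrics.percent_rna_coding = pct(rna_mask.sum() / n)
        metrics.percent_coding = pct((cds_mask | rna_mask).sum() / n)
    return metrics


# ---------------------------------------------------------------------------
# Pseudogene scanning

@dataclass(frozen=True)
class PseudogeneCall:
    gene: str
    internal_stop_count: int
    stop_codon_positions: tuple[int, ...]  # 1-based codon indices
    frame_used: int
    frame_anomaly: bool = False


def _feature_cds_residues(genome: NucleotideSequence, feature: Feature) -> str:
    parts = []
    for r in feature.intervals:
        chunk = genome.residues[r.start : r.end]
        parts.append(revcomp(chunk) if feature.strand == "-" else chunk)
    return "".join(parts)


def scan_pseudogenes(
    genome: NucleotideSequence, features: FeatureTable
) -> list[PseudogeneCall]:
    """Translate every CDS in its annotated frame (plastid/bacterial code) and
    report those with in-frame stop codons before the final codon."""
    calls = []
    for f in features.features:
        if f.kind != "CDS":
            continue
        residues = _feature_cds_residues(genome, f)
        coding_len = len(residues) - (f.codon_start - 1)
        anomaly = coding_len % 3 != 0
        protein = translate_cds(residues, f.codon_start)
        if protein.endswith("*"):
            protein = protein[:-1]
        stops = tuple(i + 1 for i, aa in enumerate(protein) if aa == "*")
        if stops:
            calls.append(
                PseudogeneCall(
                    gene=f.gene,
                    internal_stop_count=len(stops),
                    stop_codon_positions=stops,
                    frame_used=f.codon_start,
                    frame_anomaly=anomaly,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# IR boundaries / expansion

@dataclass
class IRBoundaryReport:
    junction_genes: dict[str, list[str]]
    boundary_gene: str
    boundary_gene_status: str  # full copy / partial pseudogene / absent
    ir_copy_length: int | None
    full_copy_length: int | None
    ir_expansion_flag: bool | None
    expansion_length: int | None


def analyze_ir_boundaries(
    genome: NucleotideSequence,
    structure: QuadripartiteStructure,
    features: FeatureTable,
    boundary_gene: str = "ycf1",
    comparator_ir_length: int | None = None,
    expansion_threshold: int = 1000,
    seed_k: int = 31,
    min_partial: int = 100,
) -> IRBoundaryReport:
    """Report genes spanning each junction and size the IR-internal copy of
    the designated boundary gene by anchoring the single-copy full gene into
    the IR; flag IR expansion against an explicit comparator length."""
    junctions = {
        "LSC-IRa": structure.ira[0].start,
        "IRa-SSC": structure.ssc[0].start,
        "SSC-IRb": structure.irb[0].start,
        "IRb-LSC": structure.irb[-1].end % structure.genome_length,
    }
    junction_genes: dict[str, list[str]] = {name: [] for name in junctions}
    for name, pos in junctions.items():
        for f in features.features:
            lo, hi = f.span
            if lo < pos < hi:
                junction_genes[name].append(f.gene)

    status, ir_copy_len, full_len = "absent", None, None
    full = next((f for f in features.features if f.gene == boundary_gene), None)
    if full is not None:
        gene_seq = _feature_cds_residues(genome, full)
        full_len = len(gene_seq)
        ir_seq = structure.region_sequence(genome, "ira")
        covered = _anchored_coverage(gene_seq, ir_seq, seed_k)
        rc_covered = _anchored_coverage(revcomp(gene_seq), ir_seq, seed_k)
        ir_copy_len = max(covered, rc_covered)
        if ir_copy_len >= 0.95 * full_len:
            status = "full copy"
        elif ir_copy_len >= min_partial:
            status = f"partial pseudogene ({ir_copy_len} nt)"
        else:
            status, ir_copy_len = "absent", None

    flag = expansion = None
    if comparator_ir_length is not None:
        expansion = structure.ir_length - comparator_ir_length
        flag = expansion > expansion_threshold
    return IRBoundaryReport(
        junction_genes=junction_genes,
        boundary_gene=boundary_gene,
        boundary_gene_status=status,
        ir_copy_length=ir_copy_len,
        full_copy_length=full_len,
        ir_expansion_flag=flag,
        expansion_length=expansion,
    )


def _anchored_coverage(query: str, subject: str, k: int) -> int:
    """Length of the longest run of query positions covered by exact k-mers
    shared with the subject (a gap-free proxy for the matched copy length)."""
    subject_kmers = kmer_set(subject, k)
    covered = np.zeros(len(query), dtype=bool)
    for i in range(len(query) - k + 1):
        if query[i : i + k] in subject_kmers:
            covered[i : i + k] = True
    best = run = 0
    for c in covered:
        run = run + 1 if c else 0
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# Pairwise whole-genome comparison

@dataclass(frozen=True)
class Variant:
    pos_a: int  # 0-based position on genome A
    ref: str
    alt: str
    kind: str  # snp / insertion / deletion


@dataclass
class PairwiseComparison:
    snp_count: int
    indel_event_count: int
    indel_bases: int
    percent_identity: float
    applied_flips: object | None
    variants: list[Variant] = field(default_factory=list)


_ANCHOR_K = 31


def _unique_kmer_positions(residues: str, k: int) -> dict[str, int]:
    counts: Counter = Counter()
    pos: dict[str, int] = {}
    for i in range(len(residues) - k + 1):
        kmer = residues[i : i + k]
        counts[kmer] += 1
        pos[kmer] = i
    return {kmer: p for kmer, p in pos.items() if counts[kmer] == 1}


def _chain_anchors(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of anchor pairs strictly increasing in both genomes."""
    pairs.sort()
    tails: list[int] = []
    backptr: list[int] = []
    idx_at: list[int] = []
    for i, (_, b) in enumerate(pairs):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            idx_at.append(i)
        else:
            tails[j] = b
            idx_at[j] = i
        backptr.append(idx_at[j - 1] if j > 0 else -1)
    chain = []
    i = idx_at[-1] if idx_at else -1
    while i >= 0:
        chain.append(pairs[i])
        i = backptr[i]
    return chain[::-1]


def _gap_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def pairwise_compare(
    genome_a: NucleotideSequence,
    genome_b: NucleotideSequence,
    normalize: bool = True,
    min_identity: float = 60.0,
) -> PairwiseComparison:
    """Anchor-based whole-genome comparison.

    Orientation of B is normalized against A, unique shared 31-mers are
    chained co-linearly, and inter-anchor gaps are aligned globally. A SNP is
    an aligned column with differing unambiguous bases; an indel event is a
    maximal run of gap columns.
    """
    flips = None
    a_res, b_res = genome_a.residues, genome_b.residues
    if normalize:
        structure_a = detect_inverted_repeats(genome_a)
        genome_a_n, structure_a, _ = normalize_orientation(genome_a, structure_a)
        genome_b_n, _, flips = normalize_orientation(
            genome_b, reference=genome_a_n
        )
        a_res, b_res = genome_a_n.residues, genome_b_n.residues

    ua = _unique_kmer_positions(a_res, _ANCHOR_K)
    ub = _unique_kmer_positions(b_res, _ANCHOR_K)
    pairs = [(pa, ub[kmer]) for kmer, pa in ua.items() if kmer in ub]
    if not pairs:
        raise ComparisonError("no shared unique anchors; genomes unalignable")
    chain = _chain_anchors(pairs)

    # collapse chained anchors into co-diagonal blocks, dropping conflicts
    blocks: list[tuple[int, int, int]] = []  # (a_start, b_start, length)
    for pa, pb in chain:
        if blocks:
            a0, b0, ln = blocks[-1]
            if pa - (a0 + ln - _ANCHOR_K) == pb - (b0 + ln - _ANCHOR_K) and 0 < pa - (a0 + ln - _ANCHOR_K) <= _ANCHOR_K:
                step = pa - (a0 + ln - _ANCHOR_K)
                blocks[-1] = (a0, b0, ln + step)
                continue
            if pa < a0 + ln or pb < b0 + ln:
                continue  # overlapping anchor off the block diagonal
        blocks.append((pa, pb, _ANCHOR_K))

    aligner = _gap_aligner()
    matches = mismatches = gap_cols = indel_events = 0
    variants: list[Variant] = []
    prev_a = prev_b = 0
    for a0, b0, ln in blocks + [(len(a_res), len(b_res), 0)]:
        seg_a = a_res[prev_a:a0]
        seg_b = b_res[prev_b:b0]
        m, mm, gc, ev, var = _align_gap(aligner, seg_a, seg_b, prev_a)
        matches += m + ln
        mismatches += mm
        gap_cols += gc
        indel_events += ev
        variants.extend(var)
        prev_a, prev_b = a0 + ln, b0 + ln

    columns = matches + mismatches + gap_cols
    identity = 100 * matches / columns if columns else 0.0
    if identity < min_identity:
        raise ComparisonError(f"alignment identity {identity:.1f}% below {min_identity}%")
    return PairwiseComparison(
        snp_count=mismatches,
        indel_event_count=indel_events,
        indel_bases=gap_cols,
        percent_identity=round(identity, 2),
        applied_flips=flips,
        variants=variants,
    )


def _align_gap(aligner, seg_a: str, seg_b: str, offset_a: int):
    if not seg_a and not seg_b:
        return 0, 0, 0, 0, []
    if not seg_a or not seg_b:
        kind = "insertion" if not seg_a else "deletion"
        gap_len = len(seg_a) + len(seg_b)
        return 0, 0, gap_len, 1, [Variant(offset_a, seg_a or "-", seg_b or "-", kind)]
    if len(seg_a) * len(seg_b) > 25_000_000:
        raise ComparisonError(
            f"inter-anchor segment too large to align ({len(seg_a)} x {len(seg_b)})"
        )
    alignment = aligner.align(seg_a, seg_b)[0]
    matches = mismatches = gap_cols = events = 0
    variants = []
    a_aln, b_aln = str(alignment[0]), str(alignment[1])
    in_gap = False
    pos_a = offset_a
    for ca, cb in zip(a_aln, b_aln):
        if ca == "-" or cb == "-":
            gap_cols += 1
            if not in_gap:
                events += 1
                variants.append(
                    Variant(pos_a, ca if ca != "-" else "-", cb if cb != "-" else "-",
                            "deletion" if cb == "-" else "insertion")
                )
            in_gap = True
        else:
            in_gap = False
            if ca == cb:
                matches += 1
            else:
                mismatches += 1
                variants.append(Variant(pos_a, ca, cb, "snp"))
        if ca != "-":
            pos_a += 1
    return matches, mismatches, gap_cols, events, variants


# ---------------------------------------------------------------------------
# Foreign (mitochondrion-derived) insert detection

@dataclass(frozen=True)
class ForeignInsertCall:
    interval: GenomeRegion
    classification: str  # mito-like / unclassified
    mito_identity: float
    plastid_identity: float
    flanking_genes: tuple[str, str]


def _collection_index(refs: list[NucleotideSequence], k: int):
    return [(r.residues, kmer_index(r.residues, k)) for r in refs]


def _window_identity(window: str, collection, k: int, aligner) -> float:
    """Best seeded local-alignment identity of the window against a reference
    collection; 0.0 when no exact k-mer seed exists on either strand."""
    best = 0.0
    for query in (window, revcomp(window)):
        for residues, index in collection:
            seed_ref = None
            for off in range(0, len(query) - k + 1, max(1, k // 2)):
                hits = index.get(query[off : off + k])
                if hits:
                    seed_ref = hits[0] - off
                    break
            if seed_ref is None:
                continue
            lo = max(0, seed_ref - 50)
            hi = min(len(residues), seed_ref + len(query) + 50)
            alignment = aligner.align(residues[lo:hi], query)
            if len(alignment) == 0:
                continue
            aln = alignment[0]
            a_str, b_str = str(aln[0]), str(aln[1])
            m = sum(1 for x, y in zip(a_str, b_str) if x == y and x != "-")
            identity = m / len(a_str) if a_str else 0.0
            best = max(best, identity)
    return best


def detect_foreign_insert(
    genome: NucleotideSequence,
    plastid_refs: list[NucleotideSequence],
    mito_refs: list[NucleotideSequence],
    window: int = 500,
    step: int = 250,
    min_insert: int = 1000,
    identity_threshold: float = 0.70,
    seed_k: int = 21,
    features: FeatureTable | None = None,
) -> list[ForeignInsertCall]:
    """Windowed homology classification against plastid and mitochondrial
    reference collections; adjacent non-plastid windows are merged and runs
    >= min_insert are reported with base-resolution boundary refinement."""
    if not plastid_refs or not mito_refs:
        raise ValueError("both reference collections must be non-empty")
    g = genome.residues
    n = len(g)
    plastid_idx = _collection_index(plastid_refs, seed_k)
    mito_idx = _collection_index(mito_refs, seed_k)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -3

    starts = list(range(0, max(1, n - window + 1), step))
    labels: list[tuple[int, int, str, float, float]] = []
    for s in starts:
        win = g[s : s + window]
        p_id = _window_identity(win, plastid_idx, seed_k, aligner)
        m_id = _window_identity(win, mito_idx, seed_k, aligner)
        if m_id > p_id and m_id > identity_threshold:
            label = "mito-like"
        elif p_id >= identity_threshold and p_id >= m_id:
            label = "plastid"
        else:
            label = "unclassified"
        labels.append((s, min(n, s + window), label, p_id, m_id))

    # merge adjacent/overlapping non-plastid windows
    calls: list[ForeignInsertCall] = []
    run: list[tuple[int, int, str, float, float]] = []
    plastid_cover = _plastid_coverage_mask(g, plastid_idx, 31)
    for item in labels + [(n, n, "plastid", 1.0, 0.0)]:
        if item[2] != "plastid" and (not run or item[0] <= run[-1][1]):
            run.append(item)
            continue
        if run:
            call = _finalize_insert_call(
                genome, run, plastid_cover, min_insert, features
            )
            if call is not None:
                calls.append(call)
            run = []
        if item[2] != "plastid":
            run = [item]
    return calls


def _plastid_coverage_mask(g: str, plastid_idx, k: int) -> np.ndarray:
    """Genome positions covered by an exact k-mer shared with any plastid ref."""
    covered = np.zeros(len(g), dtype=bool)
    shared: set[str] = set()
    for residues, _ in plastid_idx:
        shared |= kmer_set(residues, k)
        shared |= kmer_set(revcomp(residues), k)
    for i in range(len(g) - k + 1):
        if g[i : i + k] in shared:
            covered[i : i + k] = True
    return covered


def _finalize_insert_call(
    genome, run, plastid_cover: np.ndarray, min_insert: int, features
) -> ForeignInsertCall | None:
    start, end = run[0][0], run[-1][1]
    # boundary refinement: the insert is the maximal stretch around the core
    # not covered by any plastid-shared 31-mer
    core = (start + end) // 2
    lo, hi = start, end
    uncovered = ~plastid_cover
    if not uncovered[core]:
        idx = np.flatnonzero(uncovered[start:end])
        if idx.size == 0:
            return None
        core = start + int(idx[0])
    lo = core
    while lo > 0 and uncovered[lo - 1]:
        lo -= 1
    hi = core + 1
    while hi < len(uncovered) and uncovered[hi]:
        hi += 1
    if hi - lo < min_insert:
        return None
    mito_best = max(item[4] for item in run)
    plastid_best = max(item[3] for item in run)
    classification = "mito-like" if any(i[2] == "mito-like" for i in run) else "unclassified"
    left_gene = right_gene = ""
    if features is not None:
        before = [f for f in features.features if f.span[1] <= lo]
        after = [f for f in features.features if f.span[0] >= hi]
        if before:
            left_gene = max(before, key=lambda f: f.span[1]).gene
        if after:
            right_gene = min(after, key=lambda f: f.span[0]).gene
    return ForeignInsertCall(
        interval=GenomeRegion(genome.id, lo, hi, label="foreign_insert"),
        classification=classification,
        mito_identity=mito_best,
        plastid_identity=plastid_best,
        flanking_genes=(left_gene, right_gene),
    )


# ---------------------------------------------------------------------------
# Coverage consistency of an insert

@dataclass(frozen=True)
class ConsistencyVerdict:
    verdict: str  # consistent / inconsistent
    ratio: float
    insert_mean: float
    flank_mean: float


def coverage_consistency_check(
    insert_call: ForeignInsertCall,
    profile: CoverageProfile,
    flank: int = 5000,
    max_fold: float = 2.0,
) -> ConsistencyVerdict:
    """Compare mean depth inside the insert with its flanks; 'consistent'
    when within ``max_fold`` either way (supports genuine residency)."""
    lo, hi = insert_call.interval.start, insert_call.interval.end
    depth = profile.depth
    insert_mean = float(depth[lo:hi].mean()) if hi > lo else 0.0
    left = depth[max(0, lo - flank) : lo]
    right = depth[hi : hi + flank]
    flank_vals = np.concatenate([left, right]) if len(left) or len(right) else np.array([0.0])
    flank_mean = float(flank_vals.mean()) if flank_vals.size else 0.0
    if flank_mean == 0:
        ratio = float("inf") if insert_mean > 0 else 0.0
    else:
        ratio = insert_mean / flank_mean
    verdict = "consistent" if (1 / max_fold) <= ratio <= max_fold else "inconsistent"
    return ConsistencyVerdict(
        verdict=verdict, ratio=round(ratio, 3),
        insert_mean=insert_mean, flank_mean=flank_mean,
    )
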