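"""Read mapping and coverage QC.

Scoring follows assembler-style costs reinterpreted as penalties: match +1,
mismatch -2, gap -3 per base, local alignment (free clipping of read ends).
A read is accepted when its aligned fraction and identity meet the length /
similarity thresholds (inclusive). Reads tying across the two identical IR
copies are placed at BOTH locations by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner

from ._seeds import kmer_index
from .quadripartite import QuadripartiteStructure
from .seqio import GenomeRegion, NucleotideSequence, revcomp


@dataclass(frozen=True)
class MappingParameters:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    length_fraction: float = 0.8
    similarity_fraction: float = 0.9

    def __post_init__(self) -> None:
        for name in ("length_fraction", "similarity_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("mismatch_cost", "insertion_cost", "deletion_cost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")


STRICT_PARAMETERS = MappingParameters(length_fraction=0.99, similarity_fraction=0.99)


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    ref_interval: GenomeRegion
    strand: str
    matches: int
    mismatches: int
    insertions: int
    deletions: int
    aligned_read_fraction: float
    identity: float
    score: float


def accept_alignment(aln: ReadAlignment, params: MappingParameters) -> bool:
    """Inclusive thresholds: aligned fraction >= length_fraction AND
    identity >= similarity_fraction."""
    return (
        aln.aligned_read_fraction >= params.length_fraction
        and aln.identity >= params.similarity_fraction
    )


# ---------------------------------------------------------------------------
# Alignment engine

SEED_K = 21
_EXHAUSTIVE_CELL_LIMIT = 100_000  # below this, skip seeding and scan everything


def _make_aligner(params: MappingParameters) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -params.mismatch_cost
    # linear gap penalties; deletion consumes reference, insertion consumes read
    aligner.open_internal_deletion_score = -params.deletion_cost
    aligner.extend_internal_deletion_score = -params.deletion_cost
    aligner.open_internal_insertion_score = -params.insertion_cost
    aligner.extend_internal_insertion_score = -params.insertion_cost
    return aligner


class ReferenceIndex:
    """Seed index over a reference for repeated read alignment."""

    def __init__(self, reference: NucleotideSequence | str, k: int = SEED_K):
        self.residues = (
            reference.residues if isinstance(reference, NucleotideSequence) else reference
        )
        self.seq_id = reference.id if isinstance(reference, NucleotideSequence) else "ref"
        self.k = k
        self.index = kmer_index(self.residues, k)

    def candidate_windows(self, read: str, pad: int = 16) -> list[tuple[int, int]]:
        """Reference windows likely to contain the read, from exact seed hits."""
        k, n = self.k, len(self.residues)
        if len(read) < k:
            return []
        diagonals: set[int] = set()
        stride = max(1, (len(read) - k) // 4 or 1)
        offsets = list(range(0, len(read) - k + 1, stride))
        if offsets[-1] != len(read) - k:
            offsets.append(len(read) - k)
        for off in offsets:
            for pos in self.index.get(read[off : off + k], ()):
                diagonals.add(pos - off)
        windows = []
        for d in sorted(diagonals):
            start = max(0, d - pad)
            end = min(n, d + len(read) + pad)
            if windows and start <= windows[-1][1]:
                windows[-1] = (windows[-1][0], max(windows[-1][1], end))
            else:
                windows.append((start, end))
        return windows


def _score_window(
    aligner: PairwiseAligner, window: str, read: str
) -> tuple[float, object] | None:
    alignments = aligner.align(window, read)
    if len(alignments) == 0:
        return None
    best = alignments[0]
    if best.score <= 0:
        return None
    return best.score, best


def _stats_from_alignment(
    alignment, read_id: str, read_len: int, strand: str, seq_id: str, offset: int
) -> ReadAlignment:
    t_blocks, q_blocks = alignment.aligned
    target = alignment.target
    query = alignment.query
    matches = mismatches = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    aligned_block = sum(int(te - ts) for ts, te in t_blocks)
    deletions = t_span - aligned_block  # read gap columns consuming reference
    insertions = q_span - aligned_block  # reference gap columns consuming read
    columns = matches + mismatches + insertions + deletions
    return ReadAlignment(
        read_id=read_id,
        ref_interval=GenomeRegion(
            seq_id, offset + int(t_blocks[0][0]), offset + int(t_blocks[-1][1]),
            strand=strand, label="alignment",
        ),
        strand=strand,
        matches=matches,
        mismatches=mismatches,
        insertions=insertions,
        deletions=deletions,
        aligned_read_fraction=q_span / read_len,
        identity=matches / columns if columns else 0.0,
        score=float(alignment.score),
    )


def best_alignments(
    read: NucleotideSequence,
    reference: NucleotideSequence | ReferenceIndex,
    params: MappingParameters = MappingParameters(),
) -> list[ReadAlignment]:
    """All co-optimal placements of the read (used for IR double-placement)."""
    if len(read) < 20:
        raise ValueError(f"read {read.id!r} shorter than 20 nt")
    index = (
        reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    )
    aligner = _make_aligner(params)
    read_len = len(read)
    exhaustive = len(index.residues) * read_len <= _EXHAUSTIVE_CELL_LIMIT

    scored: list[tuple[float, int, int, str, object, int]] = []
    for strand, residues in (("+", read.residues), ("-", revcomp(read.residues))):
        if exhaustive:
            windows = [(0, len(index.residues))]
        else:
            windows = index.candidate_windows(residues)
        for start, end in windows:
            hit = _score_window(aligner, index.residues[start:end], residues)
            if hit is None:
                continue
            score, alignment = hit
            ref_start = start + int(alignment.aligned[0][0][0])
            scored.append(
                (score, ref_start, 0 if strand == "+" else 1, strand, alignment, start)
            )
    if not scored:
        return []
    best_score = max(s[0] for s in scored)
    # ties broken by leftmost reference start, then + strand; equal-score hits
    # at distinct reference positions are all returned
    winners = sorted(
        (s for s in scored if s[0] == best_score), key=lambda s: (s[1], s[2])
    )
    out = []
    seen: set[tuple[int, str]] = set()
    for score, ref_start, _, strand, alignment, offset in winners:
        key = (ref_start, strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            _stats_from_alignment(
                alignment, read.id, read_len, strand, index.seq_id, offset
            )
        )
    return out


def align_read(
    read: NucleotideSequence,
    reference: NucleotideSequence | ReferenceIndex,
    params: MappingParameters = MappingParameters(),
) -> ReadAlignment | None:
    """Best-scoring placement of the read, or None when unalignable."""
    hits = best_alignments(read, reference, params)
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# Coverage

@dataclass
class CoverageProfile:
    depth: np.ndarray
    mapped_read_count: int
    total_read_count: int

    @property
    def min_depth(self) -> int:
        return int(self.depth.min())

    @property
    def max_depth(self) -> int:
        return int(self.depth.max())

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())


@dataclass(frozen=True)
class LowCoverageRegion:
    interval: GenomeRegion
    min_depth_in_interval: int
    threshold: int = 40


def compute_coverage(
    reads: Iterable[NucleotideSequence],
    reference: NucleotideSequence | ReferenceIndex,
    params: MappingParameters = MappingParameters(),
    multimap: str = "both",
) -> CoverageProfile:
    """Depth of accepted alignments over every reference base.

    ``multimap='both'`` places an equal-best-tied read at every tied location
    (IR copies each receive the read); ``'first'`` keeps only the leftmost.
    """
    index = (
        reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    )
    depth = np.zeros(len(index.residues), dtype=np.int64)
    mapped = total = 0
    for read in reads:
        total += 1
        hits = best_alignments(read, index, params)
        hits = [h for h in hits if accept_alignment(h, params)]
        if not hits:
            continue
        mapped += 1
        if multimap == "first":
            hits = hits[:1]
        for h in hits:
            depth[h.ref_interval.start : h.ref_interval.end] += 1
    return CoverageProfile(depth=depth, mapped_read_count=mapped, total_read_count=total)


def screen_low_coverage(
    profile: CoverageProfile, threshold: int = 40, seq_id: str = "ref"
) -> list[LowCoverageRegion]:
    """Maximal runs of bases with depth strictly below the threshold."""
    low = profile.depth < threshold
    if not low.any():
        return []
    boundaries = np.flatnonzero(np.diff(low.astype(np.int8)))
    starts = [0] if low[0] else []
    starts += [int(b) + 1 for b in boundaries if low[b + 1]]
    ends = [int(b) + 1 for b in boundaries if low[b]]
    if low[-1]:
        ends.append(len(low))
    return [
        LowCoverageRegion(
            interval=GenomeRegion(seq_id, s, e, label="low_coverage"),
            min_depth_in_interval=int(profile.depth[s:e].min()),
            threshold=threshold,
        )
        for s, e in zip(starts, ends)
    ]


def remap_circular_junction(
    reads: Sequence[NucleotideSequence],
    genome: NucleotideSequence,
    structure: QuadripartiteStructure,
    window: int = 2000,
    params: MappingParameters = MappingParameters(),
) -> CoverageProfile:
    """Remap reads to (IRb tail + LSC head) to resolve the artifactual
    coverage drop at the circular origin."""
    irb = structure.region_sequence(genome, "irb")
    lsc = structure.region_sequence(genome, "lsc")
    w = window
    if w > len(irb) or w > len(lsc):
        w = min(len(irb), len(lsc))
        warnings.warn(
            f"window {window} exceeds a region length; truncated to {w}", stacklevel=2
        )
    segment = NucleotideSequence(
        id="IRb-LSC-junction", residues=irb[-w:] + lsc[:w], circular=False
    )
    return compute_coverage(reads, segment, params)


@dataclass
class DualStringencyReport:
    default_profile: CoverageProfile
    strict_profile: CoverageProfile

    @property
    def min_delta(self) -> int:
        return self.default_profile.min_depth - self.strict_profile.min_depth

    @property
    def mean_delta(self) -> float:
        return self.default_profile.mean_depth - self.strict_profile.mean_depth


def dual_stringency_report(
    reads: Sequence[NucleotideSequence],
    genome: NucleotideSequence,
    default_params: MappingParameters = MappingParameters(),
    strict_params: MappingParameters = STRICT_PARAMETERS,
) -> DualStringencyReport:
    index = ReferenceIndex(genome)
    return DualStringencyReport(
        default_profile=compute_coverage(reads, index, default_params),
        strict_profile=compute_coverage(reads, index, strict_params),
    )
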