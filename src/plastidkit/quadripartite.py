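"""Quadripartite plastome finishing: IR detection, contig classification,
junction-overlap stitching and orientation normalization.

The model genome is circular, stored linearly as LSC + IRa + SSC + IRb in the
canonical form; the two IR copies are reverse complements of each other. Draft
assemblies arrive as three contigs (LSC, one IR copy, SSC) whose termini share
short suffix-prefix overlaps across each of the four junctions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

from . import _seeds
from .seqio import GenomeRegion, NucleotideSequence, revcomp


class NoInvertedRepeatError(ValueError):
    """No reverse-complement segment pair of qualifying length was found."""


class ClassificationError(ValueError):
    pass


class StitchingError(ValueError):
    pass


class OrientationError(ValueError):
    pass


@dataclass(frozen=True)
class IRDetectionParams:
    min_ir_length: int = 1000
    seed_length: int = 31
    max_mismatch_fraction: float = 0.001

    def __post_init__(self) -> None:
        if not (self.min_ir_length > self.seed_length > 0):
            raise ValueError("require min_ir_length > seed_length > 0")


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/IRa/SSC/IRb layout of a circular genome.

    Each region is held as one or two GenomeRegion parts (two when it crosses
    the linear origin); parts are in transcription/genome order.
    """

    lsc: tuple[GenomeRegion, ...]
    ira: tuple[GenomeRegion, ...]
    ssc: tuple[GenomeRegion, ...]
    irb: tuple[GenomeRegion, ...]
    genome_length: int

    def __post_init__(self) -> None:
        if self.total_length != self.genome_length:
            raise ValueError(
                f"region lengths sum to {self.total_length}, expected {self.genome_length}"
            )
        if self.lsc_length < self.ssc_length:
            raise ValueError("LSC must be at least as long as SSC")

    @property
    def total_length(self) -> int:
        return sum(len(r) for name in ("lsc", "ira", "ssc", "irb")
                   for r in getattr(self, name))

    @property
    def lsc_length(self) -> int:
        return sum(len(r) for r in self.lsc)

    @property
    def ssc_length(self) -> int:
        return sum(len(r) for r in self.ssc)

    @property
    def ir_length(self) -> int:
        return sum(len(r) for r in self.ira)

    @property
    def lsc_start(self) -> int:
        return self.lsc[0].start

    def regions(self) -> list[GenomeRegion]:
        """All region parts, LSC first then IRa, SSC, IRb."""
        return [*self.lsc, *self.ira, *self.ssc, *self.irb]

    def region_sequence(self, genome: NucleotideSequence, name: str) -> str:
        return "".join(genome.residues[r.start : r.end] for r in getattr(self, name))

    def label_of(self, pos: int) -> str:
        for name in ("lsc", "ira", "ssc", "irb"):
            for r in getattr(self, name):
                if r.contains(pos):
                    return r.label
        raise IndexError(pos)


@dataclass(frozen=True)
class JunctionOverlap:
    junction: str  # LSC-IRa, IRa-SSC, SSC-IRb, IRb-LSC
    length: int
    sequence: str
    mismatches: int

    @property
    def in_expected_range(self) -> bool:
        # diagnostic flag only: the empirical 19-51 nt range seen in practice
        return 19 <= self.length <= 51


@dataclass(frozen=True)
class JunctionGap:
    junction: str
    left_flank: str   # residues upstream of the gap (primer-design window)
    right_flank: str  # residues downstream of the gap
    note: str = ""


@dataclass
class StitchReport:
    genome: NucleotideSequence
    structure: QuadripartiteStructure | None
    overlaps: list[JunctionOverlap]
    gaps: list[JunctionGap]
    ir_was_flipped: bool


JUNCTIONS = ("LSC-IRa", "IRa-SSC", "SSC-IRb", "IRb-LSC")


# ---------------------------------------------------------------------------
# IR detection

def detect_inverted_repeats(
    genome: NucleotideSequence, params: IRDetectionParams = IRDetectionParams()
) -> QuadripartiteStructure:
    """Locate the maximal inverted-repeat pair and label the four regions.

    Seeds exact ``seed_length``-mers of the genome against its own reverse
    complement, groups seed pairs by anti-diagonal, takes the anti-diagonal
    with the longest co-linear extent and extends it outward (tolerating up to
    ``max_mismatch_fraction`` mismatches). The longer single-copy region is
    labeled LSC; IRa is the IR copy following the LSC in circular order.
    """
    g = genome.residues
    n = len(g)
    k = params.seed_length
    if n <= 2 * params.min_ir_length:
        raise NoInvertedRepeatError(
            f"genome length {n} too short for min_ir_length {params.min_ir_length}"
        )

    index = _seeds.kmer_index(g, k)
    rc = revcomp(g)
    # pair (i, j): g[i:i+k] == revcomp(g[j:j+k]); anti-diagonal i + j is
    # constant along one inverted-repeat arm
    by_anti: dict[int, list[int]] = defaultdict(list)
    for p in range(n - k + 1):
        hits = index.get(rc[p : p + k])
        if not hits:
            continue
        j = n - p - k
        for i in hits:
            if i < j:
                by_anti[i + j].append(i)

    best: tuple[int, int, int] | None = None  # (run_length, anti, run_start)
    max_seed_gap = 3 * k  # mismatches break exact seeds; bridge short gaps
    for anti, positions in by_anti.items():
        positions.sort()
        run_start = positions[0]
        prev = positions[0]
        for i in positions[1:] + [None]:
            if i is not None and i - prev <= max_seed_gap:
                prev = i
                continue
            run_len = prev - run_start + k
            if best is None or run_len > best[0]:
                best = (run_len, anti, run_start)
            if i is not None:
                run_start = prev = i
    if best is None:
        raise NoInvertedRepeatError("no inverted repeat detected")

    run_len, anti, i0 = best
    i1 = i0 + run_len  # copy1 = [i0, i1)
    j0, j1 = anti - i1 + k, anti - i0 + k  # copy2 = [j0, j1)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # extend outward: copy1 grows left as copy2 grows right, and vice versa;
    # a mismatch is only crossed when the budget allows AND a confirm-run of
    # exact matches follows (prevents chance creep past the true boundary)
    confirm = 16
    budget = lambda length: int(params.max_mismatch_fraction * length)
    mismatches = sum(1 for a, b in zip(g[i0:i1], revcomp(g[j0:j1])) if a != b)
    while i0 > 0 and j1 < n:
        if comp.get(g[i0 - 1]) == g[j1]:
            i0 -= 1
            j1 += 1
            continue
        if mismatches + 1 > budget(i1 - i0 + 1):
            break
        run = min(confirm, i0 - 1, n - j1 - 1)
        if run < confirm or any(
            comp.get(g[i0 - 2 - t]) != g[j1 + 1 + t] for t in range(run)
        ):
            break
        i0 -= 1
        j1 += 1
        mismatches += 1
    while i1 < j0 and comp.get(g[i1]) == g[j0 - 1]:
        i1 += 1
        j0 -= 1

    if i1 - i0 < params.min_ir_length:
        raise NoInvertedRepeatError(
            f"longest inverted-repeat pair is {i1 - i0} nt, "
            f"below min_ir_length {params.min_ir_length}"
        )

    return _build_structure(genome.id, n, i0, i1, j0, j1)


def _build_structure(
    seq_id: str, n: int, c1s: int, c1e: int, c2s: int, c2e: int
) -> QuadripartiteStructure:
    """Assemble a QuadripartiteStructure from the two IR copy intervals."""
    between_len = c2s - c1e
    wrap_len = (n - c2e) + c1s
    if wrap_len >= between_len:
        # wrapping single-copy region is the LSC; copy1 follows it -> IRa
        lsc = _wrap_parts(seq_id, c2e, c1s, n, "LSC")
        ira = (GenomeRegion(seq_id, c1s, c1e, label="IRa"),)
        ssc = (GenomeRegion(seq_id, c1e, c2s, label="SSC"),)
        irb = (GenomeRegion(seq_id, c2s, c2e, label="IRb"),)
    else:
        lsc = (GenomeRegion(seq_id, c1e, c2s, label="LSC"),)
        ira = (GenomeRegion(seq_id, c2s, c2e, label="IRa"),)
        ssc = _wrap_parts(seq_id, c2e, c1s, n, "SSC")
        irb = (GenomeRegion(seq_id, c1s, c1e, label="IRb"),)
    return QuadripartiteStructure(lsc=lsc, ira=ira, ssc=ssc, irb=irb, genome_length=n)


def _wrap_parts(seq_id: str, start: int, end: int, n: int, label: str
                ) -> tuple[GenomeRegion, ...]:
    """Region running from ``start`` to ``end`` across the circular origin."""
    parts = []
    if start < n:
        parts.append(GenomeRegion(seq_id, start, n, label=label))
    if end > 0:
        parts.append(GenomeRegion(seq_id, 0, end, label=label))
    return tuple(parts)


# ---------------------------------------------------------------------------
# Contig classification

@dataclass(frozen=True)
class Contig:
    seq: NucleotideSequence
    label: str = "unlabeled"  # LSC, IR, SSC, other

    def __len__(self) -> int:
        return len(self.seq)


def classify_contigs(
    contigs: list[NucleotideSequence | Contig],
    reference: NucleotideSequence | None = None,
    min_length: int = 1000,
    min_overlap: int = 15,
    max_overlap: int = 200,
) -> list[Contig]:
    """Assign {LSC, IR, SSC, other} labels to draft contigs.

    With a reference, each contig is labeled by the reference region it shares
    the most 31-mers with (either orientation). Without one, the three longest
    contigs above ``min_length`` are ordered by length (longest -> LSC,
    shortest -> SSC, middle -> IR) and the assignment is verified by requiring
    the IR contig's termini to overlap both single-copy contigs.
    """
    seqs = [c.seq if isinstance(c, Contig) else c for c in contigs]
    if len(seqs) < 3:
        raise ClassificationError(f"need >= 3 contigs, got {len(seqs)}")

    if reference is not None:
        return _classify_by_reference(seqs, reference, min_length)

    eligible = sorted(
        (s for s in seqs if len(s) >= min_length), key=len, reverse=True
    )
    if len(eligible) < 3:
        raise ClassificationError("fewer than 3 contigs pass the length filter")
    if len(eligible) > 3 and len(eligible[3]) >= min_length:
        extra = eligible[3:]
        if any(len(s) >= len(eligible[2]) for s in extra):
            pass  # still take the 3 longest; remainder labeled other
    lsc_seq, ir_seq, ssc_seq = eligible[0], eligible[1], eligible[2]
    if len(lsc_seq) == len(ir_seq) or len(ir_seq) == len(ssc_seq):
        raise ClassificationError(
            "length tie among candidate contigs; cannot disambiguate "
            f"({len(lsc_seq)}/{len(ir_seq)}/{len(ssc_seq)} nt)"
        )
    # IR verification: both IR orientations must overlap the single-copy contigs
    ok = False
    for ira in (ir_seq.residues, revcomp(ir_seq.residues)):
        irb = revcomp(ira)
        if (
            _overlap_len(lsc_seq.residues, ira, min_overlap, max_overlap)
            and _overlap_len(ira, ssc_seq.residues, min_overlap, max_overlap)
            and _overlap_len(ssc_seq.residues, irb, min_overlap, max_overlap)
            and _overlap_len(irb, lsc_seq.residues, min_overlap, max_overlap)
        ):
            ok = True
            break
    if not ok:
        raise ClassificationError(
            "middle-length contig does not overlap both single-copy contigs; "
            "candidates: " + ", ".join(f"{s.id}({len(s)})" for s in eligible[:3])
        )
    labels = {id(lsc_seq): "LSC", id(ir_seq): "IR", id(ssc_seq): "SSC"}
    return [Contig(s, labels.get(id(s), "other")) for s in seqs]


def _classify_by_reference(
    seqs: list[NucleotideSequence],
    reference: NucleotideSequence,
    min_length: int,
) -> list[Contig]:
    structure = detect_inverted_repeats(reference)
    region_kmers = {
        label: _seeds.kmer_set(structure.region_sequence(reference, attr), 31)
        for attr, label in (("lsc", "LSC"), ("ira", "IR"), ("ssc", "SSC"))
    }
    out: list[Contig] = []
    claimed: dict[str, NucleotideSequence] = {}
    for s in seqs:
        if len(s) < min_length:
            out.append(Contig(s, "other"))
            continue
        scores = {}
        for label, kmers in region_kmers.items():
            fwd = _seeds.shared_kmer_fraction(s.residues, kmers, 31)
            rev = _seeds.shared_kmer_fraction(revcomp(s.residues), kmers, 31)
            scores[label] = max(fwd, rev)
        label, score = max(scores.items(), key=lambda kv: kv[1])
        if score < 0.5:
            out.append(Contig(s, "other"))
            continue
        if label in claimed:
            raise ClassificationError(
                f"contigs {claimed[label].id!r} and {s.id!r} both claim {label}"
            )
        claimed[label] = s
        out.append(Contig(s, label))
    return out


# ---------------------------------------------------------------------------
# Junction overlaps and stitching

def _overlap_len(
    left: str, right: str, min_overlap: int, max_overlap: int, max_mismatches: int = 0
) -> tuple[int, int] | None:
    """Longest suffix(left)/prefix(right) match within [min_overlap, max_overlap].

    Returns (length, mismatches) or None.
    """
    top = min(max_overlap, len(left), len(right))
    for length in range(top, min_overlap - 1, -1):
        mism = sum(1 for a, b in zip(left[-length:], right[:length]) if a != b)
        if mism <= max_mismatches:
            return length, mism
    return None


def find_junction_overlap(
    left: NucleotideSequence | str,
    right: NucleotideSequence | str,
    min_overlap: int = 15,
    max_overlap: int = 200,
    max_mismatches: int = 0,
    junction: str = "?",
) -> JunctionOverlap | None:
    left_res = left.residues if isinstance(left, NucleotideSequence) else left
    right_res = right.residues if isinstance(right, NucleotideSequence) else right
    if len(left_res) <= min_overlap or len(right_res) <= min_overlap:
        raise ValueError("both sequences must be longer than min_overlap")
    hit = _overlap_len(left_res, right_res, min_overlap, max_overlap, max_mismatches)
    if hit is None:
        return None
    length, mism = hit
    return JunctionOverlap(
        junction=junction, length=length, sequence=right_res[:length], mismatches=mism
    )


GAP_PLACEHOLDER = "N" * 100
GAP_FLANK_WINDOW = 300  # primer-walking window; low-GC stretches motivate >100 nt


def stitch_quadripartite(
    lsc: Contig | NucleotideSequence,
    ir: Contig | NucleotideSequence,
    ssc: Contig | NucleotideSequence,
    min_overlap: int = 15,
    max_overlap: int = 200,
    max_mismatches: int = 0,
    flank_window: int = GAP_FLANK_WINDOW,
) -> StitchReport:
    """Join the three labeled contigs into LSC + IRa + SSC + IRb.

    Both IR orientations are tried; the one producing overlaps at all four
    junctions (including the circular IRb->LSC junction) wins. Junctions
    without an overlap yield a JunctionGap with >=100 nt flanking windows and
    an N-run placeholder in the emitted genome. With the IR counted twice,
    the gap-free genome length equals sum(contig lengths) - sum(overlaps).
    """
    lsc_res = (lsc.seq if isinstance(lsc, Contig) else lsc).residues
    ir_res = (ir.seq if isinstance(ir, Contig) else ir).residues
    ssc_res = (ssc.seq if isinstance(ssc, Contig) else ssc).residues

    candidates = []
    for flipped, ira in ((False, ir_res), (True, revcomp(ir_res))):
        irb = revcomp(ira)
        pairs = [
            ("LSC-IRa", lsc_res, ira),
            ("IRa-SSC", ira, ssc_res),
            ("SSC-IRb", ssc_res, irb),
            ("IRb-LSC", irb, lsc_res),
        ]
        found = {}
        for name, a, b in pairs:
            hit = _overlap_len(a, b, min_overlap, max_overlap, max_mismatches)
            if hit is not None:
                found[name] = JunctionOverlap(name, hit[0], b[: hit[0]], hit[1])
        candidates.append((len(found), flipped, ira, irb, found))

    candidates.sort(key=lambda c: c[0], reverse=True)
    n_found, flipped, ira, irb, found = candidates[0]
    if n_found < 2:
        diag = "; ".join(
            f"{'revcomp' if f else 'as-given'}: {n} overlap(s)"
            for n, f, *_ in candidates
        )
        raise StitchingError(f"neither IR orientation yields >= 2 junction overlaps ({diag})")

    parts: list[str] = [lsc_res]
    gaps: list[JunctionGap] = []

    def _join(name: str, left: str, right: str) -> str:
        if name in found:
            return right[found[name].length :]
        gaps.append(
            JunctionGap(
                junction=name,
                left_flank=left[-flank_window:],
                right_flank=right[:flank_window],
                note="no junction overlap; window for primer walking",
            )
        )
        return GAP_PLACEHOLDER + right

    parts.append(_join("LSC-IRa", lsc_res, ira))
    parts.append(_join("IRa-SSC", ira, ssc_res))
    parts.append(_join("SSC-IRb", ssc_res, irb))
    rotation = 0
    if "IRb-LSC" in found:
        # the circular overlap is merged once and assigned to the IRb side;
        # rotate so the genome starts at the first LSC base after it
        trim = found["IRb-LSC"].length
        parts[-1] = parts[-1][: len(parts[-1]) - trim]
        rotation = trim
    else:
        gaps.append(
            JunctionGap(
                junction="IRb-LSC",
                left_flank=irb[-flank_window:],
                right_flank=lsc_res[:flank_window],
                note="no circular-origin overlap; window for primer walking",
            )
        )
        parts.append(GAP_PLACEHOLDER)

    residues = "".join(parts)
    if rotation:
        residues = residues[rotation:] + residues[:rotation]
    genome = NucleotideSequence(id="stitched", residues=residues, circular=True)
    structure = None
    if not gaps:
        try:
            structure = detect_inverted_repeats(genome)
        except NoInvertedRepeatError:
            structure = None
    overlaps = [found[j] for j in JUNCTIONS if j in found]
    return StitchReport(
        genome=genome, structure=structure, overlaps=overlaps, gaps=gaps,
        ir_was_flipped=flipped,
    )


# ---------------------------------------------------------------------------
# Orientation normalization

@dataclass(frozen=True)
class AppliedFlips:
    rotation: int
    lsc_flipped: bool
    ssc_flipped: bool


def rotate_genome(genome: NucleotideSequence, offset: int) -> NucleotideSequence:
    """Rotate a circular genome so that ``offset`` becomes position 0."""
    res = genome.residues
    offset %= len(res)
    return replace(genome, residues=res[offset:] + res[:offset], circular=True)


def normalize_orientation(
    genome: NucleotideSequence,
    structure: QuadripartiteStructure | None = None,
    reference: NucleotideSequence | None = None,
    min_identity: float = 0.60,
    seed_k: int = 31,
) -> tuple[NucleotideSequence, QuadripartiteStructure, AppliedFlips]:
    """Rotate to start at LSC base 1 and, given a reference, flip LSC/SSC
    independently so each single-copy region matches the reference's strand.

    Orientation of each region is decided by which strand shares more exact
    ``seed_k``-mers with the reference region; both below ``min_identity``
    raises OrientationError. Idempotent: a normalized genome maps to itself.
    """
    if structure is None:
        structure = detect_inverted_repeats(genome)
    rotation = structure.lsc_start % len(genome)
    rotated = rotate_genome(genome, rotation) if rotation else genome
    structure = detect_inverted_repeats(rotated) if rotation else structure

    lsc = structure.region_sequence(rotated, "lsc")
    ira = structure.region_sequence(rotated, "ira")
    ssc = structure.region_sequence(rotated, "ssc")
    irb = structure.region_sequence(rotated, "irb")

    lsc_flip = ssc_flip = False
    if reference is not None:
        ref_structure = detect_inverted_repeats(reference)
        for name, region_seq in (("lsc", lsc), ("ssc", ssc)):
            ref_seq = ref_structure.region_sequence(reference, name)
            fwd, rev = _seeds.orientation_identity(region_seq, ref_seq, seed_k)
            if max(fwd, rev) < min_identity:
                raise OrientationError(
                    f"{name.upper()} too diverged to orient "
                    f"(forward {fwd:.2f}, revcomp {rev:.2f} < {min_identity})"
                )
            if rev > fwd:
                if name == "lsc":
                    lsc_flip = True
                else:
                    ssc_flip = True

    if lsc_flip or ssc_flip:
        if lsc_flip:
            lsc = revcomp(lsc)
        if ssc_flip:
            ssc = revcomp(ssc)
        rotated = replace(rotated, residues=lsc + ira + ssc + irb, circular=True)
        structure = detect_inverted_repeats(rotated)
    return rotated, structure, AppliedFlips(rotation, lsc_flip, ssc_flip)
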