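"""Dispersed-repeat and microsatellite scanning.

Repeat search reports maximal repeat pairs of four kinds (forward, reverse,
complement, palindromic) with a Hamming-distance tolerance, seeded by exact
q-grams (pigeonhole: a length-L pair with <= h mismatches contains an exact
run of at least L // (h + 1)). Microsatellite scanning reports maximal
perfect tandem runs under per-unit-size minimum repeat counts, with nearby
hits merged into compound loci.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from ._seeds import kmer_index, kmer_set, shared_kmer_fraction
from .quadripartite import QuadripartiteStructure
from .seqio import GenomeRegion, NucleotideSequence, complement, revcomp

REPEAT_KINDS = ("forward", "reverse", "complement", "palindromic")


@dataclass(frozen=True)
class RepeatSearchParams:
    min_length: int = 30
    max_hamming: int = 3
    kinds: tuple[str, ...] = REPEAT_KINDS
    exclude_ir_duplicate: bool = True

    def __post_init__(self) -> None:
        if self.min_length <= self.max_hamming:
            raise ValueError("min_length must exceed max_hamming")
        bad = set(self.kinds) - set(REPEAT_KINDS)
        if bad:
            raise ValueError(f"unknown repeat kinds: {sorted(bad)}")


@dataclass(frozen=True)
class RepeatHit:
    kind: str
    copy1: GenomeRegion
    copy2: GenomeRegion
    length: int
    hamming: int


# ---------------------------------------------------------------------------
# Maximal repeat pairs

def _transformed(genome: str, kind: str) -> str:
    if kind == "forward":
        return genome
    if kind == "complement":
        return complement(genome)
    if kind == "reverse":
        return genome[::-1]
    if kind == "palindromic":
        return revcomp(genome)
    raise ValueError(kind)


def _map_back(kind: str, n: int, u: int, v: int, length: int) -> tuple[int, int] | None:
    """Map a common substring at (genome offset u, transformed offset v) back to
    a (copy1 start, copy2 start) pair in genome coordinates, or None if the
    pair is the trivial self-match."""
    if kind in ("forward", "complement"):
        j = v
    else:  # reverse, palindromic: transformed sequence runs backwards
        j = n - v - length
    if u == j and kind == "forward":
        return None
    a, b = min(u, j), max(u, j)
    return a, b


def _maximal_windows(
    mismatch_at, lo: int, hi: int, seed_lo: int, seed_hi: int,
    max_hamming: int, min_length: int,
):
    """Maximal <=h-mismatch windows within [lo, hi) that contain the seed run.

    ``mismatch_at(t)`` says whether diagonal offset t is a mismatch. Mismatch
    offsets are collected only near the seed (at most h+1 on each side), which
    is sufficient: every maximal window is bounded by its (h+1)-th mismatch or
    the diagonal ends.
    """
    left_mm: list[int] = []  # mismatch offsets < seed_lo, descending
    t = seed_lo - 1
    while t >= lo and len(left_mm) <= max_hamming:
        if mismatch_at(t):
            left_mm.append(t)
        t -= 1
    left_bound = t  # first offset NOT examined (exclusive)
    right_mm: list[int] = []
    t = seed_hi
    while t < hi and len(right_mm) <= max_hamming:
        if mismatch_at(t):
            right_mm.append(t)
        t += 1
    right_bound = t

    # index i in `lefts` bounds a window that includes exactly i left
    # mismatches; the sentinel (diagonal start/end) includes them all
    lefts = left_mm + ([lo - 1] if len(left_mm) <= max_hamming else [])
    rights = right_mm + ([hi] if len(right_mm) <= max_hamming else [])
    windows = []
    for a_used, lb in enumerate(lefts):
        for b_used, rb in enumerate(rights):
            if a_used + b_used > max_hamming:
                continue
            # maximal iff it cannot absorb one more mismatch on either side
            can_grow_left = (lb != lo - 1) and (a_used + b_used < max_hamming)
            can_grow_right = (rb != hi) and (a_used + b_used < max_hamming)
            if can_grow_left or can_grow_right:
                continue
            start, end = lb + 1, rb
            if end - start >= min_length:
                windows.append((start, end, a_used + b_used))
    return windows


def find_maximal_repeats(
    genome: NucleotideSequence,
    params: RepeatSearchParams = RepeatSearchParams(),
    structure: QuadripartiteStructure | None = None,
) -> list[RepeatHit]:
    """All maximal repeat pairs of the requested kinds.

    Each unordered pair is reported once (copy1 start <= copy2 start). When
    ``exclude_ir_duplicate`` and a structure is supplied, hits whose two
    copies sit at mirrored offsets of IRa/IRb — echoes of the quadripartite
    duplication itself — are dropped.
    """
    g = genome.residues
    n = len(g)
    if n < 2 * params.min_length:
        return []
    q = max(4, params.min_length // (params.max_hamming + 1))
    index = kmer_index(g, q)

    hits: dict[tuple, int] = {}
    for kind in params.kinds:
        t_seq = _transformed(g, kind)
        # seed pairs grouped by diagonal (v - u) in (genome, transformed) space
        diagonals: dict[int, list[int]] = defaultdict(list)
        for v in range(n - q + 1):
            for u in index.get(t_seq[v : v + q], ()):
                diagonals[v - u].append(u)
        for d, seeds in diagonals.items():
            lo = max(0, -d)
            hi = min(n, n - d)

            def mismatch_at(t: int, _d: int = d, _ts: str = t_seq) -> bool:
                return g[t] != _ts[t + _d]

            seeds.sort()
            # merge seed starts into runs, then extend each run once
            runs: list[tuple[int, int]] = []
            run_s = prev = seeds[0]
            for s in seeds[1:] + [None]:
                if s is not None and s - prev <= q:
                    prev = s
                    continue
                runs.append((run_s, prev + q))
                if s is not None:
                    run_s = prev = s
            for seed_lo, seed_hi in runs:
                for start, end, ham in _maximal_windows(
                    mismatch_at, lo, hi, seed_lo, seed_hi,
                    params.max_hamming, params.min_length,
                ):
                    length = end - start
                    mapped = _map_back(kind, n, start, start + d, length)
                    if mapped is None:
                        continue
                    a, b = mapped
                    hits[(kind, a, b, length)] = ham

    out = [
        RepeatHit(
            kind=kind,
            copy1=GenomeRegion(genome.id, a, a + length, label=kind),
            copy2=GenomeRegion(genome.id, b, b + length, label=kind),
            length=length,
            hamming=ham,
        )
        for (kind, a, b, length), ham in hits.items()
    ]
    if params.exclude_ir_duplicate and structure is not None:
        out = [h for h in out if not _is_ir_mirror(h, structure)]
    out.sort(key=lambda h: (h.copy1.start, h.copy2.start, h.kind))
    return out


def _is_ir_mirror(hit: RepeatHit, structure: QuadripartiteStructure) -> bool:
    """True when the two copies lie on the IRa/IRb mirror anti-diagonal
    (same offset from the respective IR boundaries) and overlap the IRs —
    i.e. the hit is an echo of the quadripartite duplication itself."""
    if hit.kind != "palindromic":
        return False
    if len(structure.ira) != 1 or len(structure.irb) != 1:
        return False
    ira, irb = structure.ira[0], structure.irb[0]
    if hit.copy1.end <= ira.start or hit.copy1.start >= ira.end:
        return False
    if hit.copy2.end <= irb.start or hit.copy2.start >= irb.end:
        return False
    return (hit.copy1.start - ira.start) == (irb.end - hit.copy2.end)


# ---------------------------------------------------------------------------
# Repeat genomic context

@dataclass
class RepeatLocationSummary:
    intergenic: int = 0
    exon: int = 0
    intron: int = 0

    @property
    def total(self) -> int:
        return self.intergenic + self.exon + self.intron

    def percentages(self) -> dict[str, float]:
        t = self.total or 1
        return {
            "intergenic": 100 * self.intergenic / t,
            "exon": 100 * self.exon / t,
            "intron": 100 * self.intron / t,
        }


def classify_repeat_locations(
    hits: list[RepeatHit], features, structure: QuadripartiteStructure | None = None
) -> RepeatLocationSummary:
    """Assign each hit by its copy1 midpoint: exon when inside a feature
    interval, intron when inside a feature's span but between intervals,
    else intergenic."""
    summary = RepeatLocationSummary()
    for hit in hits:
        mid = (hit.copy1.start + hit.copy1.end) // 2
        context = "intergenic"
        for feat in features.features:
            span_lo, span_hi = feat.span
            if not (span_lo <= mid < span_hi):
                continue
            if any(r.contains(mid) for r in feat.intervals):
                context = "exon"
                break
            context = "intron"
        setattr(summary, context, getattr(summary, context) + 1)
    return summary


# ---------------------------------------------------------------------------
# Microsatellites

@dataclass(frozen=True)
class SSRThresholds:
    min_repeats: tuple[int, ...] = (10, 6, 5, 3, 3, 3)  # unit sizes 1..6
    compound_max_gap: int = 100

    def __post_init__(self) -> None:
        if len(self.min_repeats) != 6 or any(m < 1 for m in self.min_repeats):
            raise ValueError("min_repeats must give six thresholds >= 1")


@dataclass(frozen=True)
class SSRHit:
    motif: str
    repeat_number: int
    interval: GenomeRegion
    klass: str  # p1..p6 or compound
    members: tuple["SSRHit", ...] = ()

    @property
    def start_1based(self) -> int:
        return self.interval.start + 1

    @property
    def end_1based(self) -> int:
        return self.interval.end


def _is_minimal_motif(motif: str) -> bool:
    """A motif must not be a whole-number repetition of a shorter motif."""
    m = len(motif)
    for p in range(1, m):
        if m % p == 0 and motif == motif[:p] * (m // p):
            return False
    return True


def find_ssrs(
    genome: NucleotideSequence, thresholds: SSRThresholds = SSRThresholds()
) -> list[SSRHit]:
    """Maximal perfect tandem runs meeting the per-unit-size thresholds.

    Motifs are minimal (an (AT)n run is di-, never a tetranucleotide
    artifact); qualifying SSRs separated by at most ``compound_max_gap``
    bases are merged into one compound hit. Reported coordinates cover
    whole repeat units only.
    """
    g = genome.residues
    n = len(g)
    simple: list[SSRHit] = []
    covered: list[tuple[int, int]] = []  # run spans already claimed by smaller units
    for m in range(1, 7):
        min_reps = thresholds.min_repeats[m - 1]
        i = 0
        while i + m <= n:
            # extend the period-m run starting at i
            j = i + m
            while j < n and g[j] == g[j - m]:
                j += 1
            run_len = j - i
            reps = run_len // m
            if reps >= min_reps:
                motif = g[i : i + m]
                if _is_minimal_motif(motif) and not any(
                    s <= i and i + reps * m <= e for s, e in covered
                ):
                    end = i + reps * m
                    simple.append(
                        SSRHit(
                            motif=motif,
                            repeat_number=reps,
                            interval=GenomeRegion(genome.id, i, end, label=f"p{m}"),
                            klass=f"p{m}",
                        )
                    )
                    covered.append((i, j))
                i = j - m + 1  # a new maximal run can start within the tail
            else:
                i += 1
    simple.sort(key=lambda h: (h.interval.start, h.interval.end))
    return _merge_compound(genome.id, simple, thresholds.compound_max_gap)


def _merge_compound(seq_id: str, hits: list[SSRHit], max_gap: int) -> list[SSRHit]:
    out: list[SSRHit] = []
    group: list[SSRHit] = []
    for hit in hits:
        if group and hit.interval.start - group[-1].interval.end <= max_gap:
            group.append(hit)
            continue
        out.extend(_finish_group(seq_id, group))
        group = [hit]
    out.extend(_finish_group(seq_id, group))
    return out


def _finish_group(seq_id: str, group: list[SSRHit]) -> list[SSRHit]:
    if not group:
        return []
    if len(group) == 1:
        return group
    start = group[0].interval.start
    end = max(h.interval.end for h in group)
    return [
        SSRHit(
            motif="+".join(h.motif for h in group),
            repeat_number=0,
            interval=GenomeRegion(seq_id, start, end, label="compound"),
            klass="compound",
            members=tuple(group),
        )
    ]


@dataclass
class SSRSummary:
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, klass: str) -> int:
        return self.counts.get(klass, 0)


def summarize_ssrs(hits: list[SSRHit]) -> SSRSummary:
    """Counts per class; a compound counts once (members not double-counted)."""
    summary = SSRSummary()
    for hit in hits:
        summary.counts[hit.klass] = summary.counts.get(hit.klass, 0) + 1
    return summary


# ---------------------------------------------------------------------------
# Cross-genome SSR comparison

@dataclass(frozen=True)
class SSRPolymorphism:
    motif: str
    interval_a: GenomeRegion | None
    interval_b: GenomeRegion | None
    repeats_a: int | None
    repeats_b: int | None

    @property
    def status(self) -> str:
        if self.interval_a is None:
            return "absent_in_a"
        if self.interval_b is None:
            return "absent_in_b"
        return "count_differs"


def compare_ssrs(
    genome_a: NucleotideSequence,
    genome_b: NucleotideSequence,
    thresholds: SSRThresholds = SSRThresholds(),
    anchor_flank: int = 200,
    seed_k: int = 31,
    min_anchor_identity: float = 0.5,
) -> list[SSRPolymorphism]:
    """Pair SSR loci across two genomes by flanking-sequence anchors and
    report loci whose repeat counts differ (or that cannot be paired)."""
    hits_a = [h for h in find_ssrs(genome_a, thresholds) if h.klass != "compound"]
    hits_b = [h for h in find_ssrs(genome_b, thresholds) if h.klass != "compound"]

    out: list[SSRPolymorphism] = []
    unmatched_b = {id(h) for h in hits_b}
    for ha in hits_a:
        flank_l = genome_a.residues[max(0, ha.interval.start - anchor_flank) : ha.interval.start]
        flank_r = genome_a.residues[ha.interval.end : ha.interval.end + anchor_flank]
        partner = None
        for hb in hits_b:
            if hb.motif != ha.motif and hb.motif != revcomp(ha.motif):
                continue
            fl_b = genome_b.residues[max(0, hb.interval.start - anchor_flank) : hb.interval.start]
            fr_b = genome_b.residues[hb.interval.end : hb.interval.end + anchor_flank]
            score = _flank_similarity(flank_l, flank_r, fl_b, fr_b, seed_k)
            if score >= min_anchor_identity:
                partner = hb
                break
        if partner is None:
            out.append(
                SSRPolymorphism(ha.motif, ha.interval, None, ha.repeat_number, None)
            )
            continue
        unmatched_b.discard(id(partner))
        if partner.repeat_number != ha.repeat_number:
            out.append(
                SSRPolymorphism(
                    ha.motif, ha.interval, partner.interval,
                    ha.repeat_number, partner.repeat_number,
                )
            )
    for hb in hits_b:
        if id(hb) in unmatched_b:
            out.append(
                SSRPolymorphism(hb.motif, None, hb.interval, None, hb.repeat_number)
            )
    return out


def _flank_similarity(al: str, ar: str, bl: str, br: str, k: int) -> float:
    scores = []
    for a, b in ((al, bl), (ar, br)):
        if len(a) >= k and len(b) >= k:
            scores.append(shared_kmer_fraction(a, kmer_set(b, k), k))
    return max(scores) if scores else 0.0
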