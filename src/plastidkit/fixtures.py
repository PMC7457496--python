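"""Deterministic synthetic plastomes with known ground truth.

Generates quadripartite genomes (LSC + IRa + SSC + IRb, IRb = revcomp(IRa))
with planted microsatellites, dispersed repeats, foreign inserts and boundary
genes; fragments them into three overlapping draft contigs; and simulates
fixed-length reads — everything seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seeds import kmer_set
from .quadripartite import QuadripartiteStructure, _build_structure, Contig
from .seqio import Feature, FeatureTable, GenomeRegion, NucleotideSequence, revcomp

BASES = np.array(list("ACGT"))


class FixtureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    repeat_number: int
    start: int  # final genome coordinates, 0-based half-open
    end: int
    region: str


@dataclass(frozen=True)
class PlantedRepeat:
    kind: str
    start1: int
    start2: int
    length: int
    hamming: int


@dataclass(frozen=True)
class PlantedInsert:
    donor: str
    start: int
    end: int
    donor_residues: str


@dataclass(frozen=True)
class PlantedBoundaryGene:
    name: str
    status: str  # full / partial
    full_interval: tuple[int, int]  # SSC full copy, genome coords
    ir_copy_length: int


@dataclass
class ElementRegistry:
    ssrs: list[PlantedSSR] = field(default_factory=list)
    repeats: list[PlantedRepeat] = field(default_factory=list)
    insert: PlantedInsert | None = None
    boundary_gene: PlantedBoundaryGene | None = None


@dataclass(frozen=True)
class PlastomeSpec:
    lsc_length: int = 84_000
    ssc_length: int = 19_000
    ir_length: int = 25_000
    gc_target: float = 0.36
    gc_by_region: dict | None = None  # optional {"lsc"/"ssc"/"ir": fraction}
    planted_ssrs: tuple = ()  # (motif, repeat_number, region)
    planted_repeats: tuple = ()  # (kind, length, hamming, region)
    planted_insert: tuple | None = None  # (donor_label, length, region)
    planted_boundary_gene: tuple | None = None  # (status, length)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lsc_length, self.ssc_length, self.ir_length) <= 0:
            raise FixtureSpecError("region lengths must be positive")
        if self.lsc_length < self.ssc_length:
            raise FixtureSpecError("lsc_length must be >= ssc_length")


def _random_region(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


_CODE = {0: "A", 1: "C", 2: "G", 3: "T"}
_RC_CODE = {0: 3, 1: 2, 2: 1, 3: 0}


def _to_str(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


class _RegionDraft:
    """Mutable per-region buffer tracking claimed intervals."""

    def __init__(self, name: str, codes: np.ndarray):
        self.name = name
        self.codes = codes
        self.claimed: list[tuple[int, int]] = []

    def reserve(self, rng: np.random.Generator, length: int, pad: int = 5) -> int:
        if length + 2 * pad >= len(self.codes):
            raise FixtureSpecError(
                f"{length} nt element exceeds capacity of region {self.name}"
            )
        for _ in range(200):
            pos = int(rng.integers(pad, len(self.codes) - length - pad))
            if all(pos + length + pad <= s or pos >= e + pad for s, e in self.claimed):
                self.claimed.append((pos, pos + length))
                return pos
        raise FixtureSpecError(
            f"cannot place a {length} nt element in region {self.name}"
        )

    def write(self, pos: int, residues: str) -> None:
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        self.codes[pos : pos + len(residues)] = [idx[c] for c in residues]


def generate_plastome(
    spec: PlastomeSpec,
) -> tuple[NucleotideSequence, QuadripartiteStructure, FeatureTable, ElementRegistry]:
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_by_region or {}
    drafts = {
        "LSC": _RegionDraft("LSC", _random_region(rng, spec.lsc_length, gc.get("lsc", spec.gc_target))),
        "IRa": _RegionDraft("IRa", _random_region(rng, spec.ir_length, gc.get("ir", spec.gc_target))),
        "SSC": _RegionDraft("SSC", _random_region(rng, spec.ssc_length, gc.get("ssc", spec.gc_target))),
    }
    registry = ElementRegistry()
    features: list[Feature] = []

    pending_ssrs = []
    for motif, reps, region in spec.planted_ssrs:
        motif = motif.upper()
        draft = drafts[region]
        length = len(motif) * reps
        pos = draft.reserve(rng, length + 2)
        draft.write(pos + 1, motif * reps)
        # flanks must break the run on both sides
        draft.codes[pos] = _pick_other(rng, motif[-1])
        draft.codes[pos + 1 + length] = _pick_other(rng, motif[0])
        pending_ssrs.append((motif, reps, region, pos + 1, pos + 1 + length))

    pending_repeats = []
    for kind, length, hamming, region in spec.planted_repeats:
        draft = drafts[region]
        copy1 = _to_str(_random_region(rng, length, spec.gc_target))
        copy2 = _transform_copy(copy1, kind)
        copy2 = _mutate(rng, copy2, hamming)
        p1 = draft.reserve(rng, length, pad=40)
        p2 = draft.reserve(rng, length, pad=40)
        p1, p2 = min(p1, p2), max(p1, p2)
        draft.write(p1, copy1)
        draft.write(p2, copy2)
        _break_repeat_flanks(rng, draft, kind, p1, p2, length)
        pending_repeats.append((kind, region, p1, p2, length, hamming))

    pending_gene = None
    if spec.planted_boundary_gene is not None:
        status, gene_len = spec.planted_boundary_gene
        gene_seq = _to_str(_random_region(rng, gene_len, spec.gc_target))
        ssc = drafts["SSC"]
        ssc.write(0, gene_seq)  # full copy at the IRa-SSC boundary
        ssc.claimed.append((0, gene_len))
        ir_copy_len = gene_len if status == "full" else min(1200, gene_len)
        ira = drafts["IRa"]
        ira_pos = len(ira.codes) - ir_copy_len
        ira.write(ira_pos, revcomp(gene_seq[:ir_copy_len]))
        ira.claimed.append((ira_pos, len(ira.codes)))
        pending_gene = (status, gene_len, ir_copy_len)

    pending_insert = None
    if spec.planted_insert is not None:
        donor_label, ins_len, region = spec.planted_insert
        host_kmers = kmer_set(
            "".join(_to_str(d.codes) for d in drafts.values()), 31
        )
        draft = drafts[region]
        pos = draft.reserve(rng, ins_len, pad=40)
        # terminal donor bases must differ from the host bases they replace,
        # otherwise a host 31-mer still covers the boundary position and the
        # insert's exact edges become ambiguous
        orig_first = _CODE[int(draft.codes[pos])]
        orig_last = _CODE[int(draft.codes[pos + ins_len - 1])]
        for attempt in range(50):
            chars = list(_to_str(_random_region(rng, ins_len, 0.45)))
            if chars[0] == orig_first:
                chars[0] = _CODE[_pick_other(rng, orig_first)]
            if chars[-1] == orig_last:
                chars[-1] = _CODE[_pick_other(rng, orig_last)]
            donor = "".join(chars)
            if not (kmer_set(donor, 31) & host_kmers):
                break
        else:
            raise FixtureSpecError("could not build a donor free of shared 31-mers")
        draft.write(pos, donor)
        pending_insert = (donor_label, region, pos, ins_len, donor)

    lsc = _to_str(drafts["LSC"].codes)
    ira = _to_str(drafts["IRa"].codes)
    ssc = _to_str(drafts["SSC"].codes)
    # the IR pair must be maximal exactly at the construction boundaries:
    # if SSC's first and last bases reverse-complemented each other, the true
    # maximal IR would extend one base into the SSC on both sides
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if ssc[-1] == comp[ssc[0]]:
        ssc = ssc[:-1] + _CODE[_pick_other(rng, comp[ssc[0]])]
    # same guard at the circular origin (LSC end vs LSC start), so rotated
    # copies of the genome also detect the IR pair at exact boundaries
    if lsc[-1] == comp[lsc[0]]:
        lsc = lsc[:-1] + _CODE[_pick_other(rng, comp[lsc[0]])]
    residues = lsc + ira + ssc + revcomp(ira)
    genome = NucleotideSequence(id=f"fixture-{spec.seed}", residues=residues, circular=True)
    n = len(residues)
    c1s, c1e = len(lsc), len(lsc) + len(ira)
    c2s = c1e + len(ssc)
    structure = _build_structure(genome.id, n, c1s, c1e, c2s, n)

    offsets = {"LSC": 0, "IRa": len(lsc), "SSC": len(lsc) + len(ira)}
    for motif, reps, region, start, end in pending_ssrs:
        registry.ssrs.append(
            PlantedSSR(motif, reps, offsets[region] + start, offsets[region] + end, region)
        )
    for kind, region, p1, p2, length, hamming in pending_repeats:
        registry.repeats.append(
            PlantedRepeat(kind, offsets[region] + p1, offsets[region] + p2, length, hamming)
        )
    if pending_insert is not None:
        donor_label, region, pos, ins_len, donor = pending_insert
        registry.insert = PlantedInsert(
            donor_label, offsets[region] + pos, offsets[region] + pos + ins_len, donor
        )
    if pending_gene is not None:
        status, gene_len, ir_copy_len = pending_gene
        g_start = offsets["SSC"]
        registry.boundary_gene = PlantedBoundaryGene(
            name="ycf1", status=status,
            full_interval=(g_start, g_start + gene_len),
            ir_copy_length=ir_copy_len,
        )
        features.append(
            Feature(
                gene="ycf1", kind="CDS",
                intervals=(GenomeRegion(genome.id, g_start, g_start + gene_len),),
                strand="+",
            )
        )
    return genome, structure, FeatureTable(seq_id=genome.id, features=features), registry


def _break_repeat_flanks(
    rng: np.random.Generator, draft: "_RegionDraft", kind: str, p1: int, p2: int, length: int
) -> None:
    """Force the bases just outside both copies to violate the repeat relation
    so the planted pair is maximal at exactly its planted coordinates."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if kind in ("forward", "complement"):
        flank_pairs = [(p1 - 1, p2 - 1), (p1 + length, p2 + length)]
    else:  # reverse, palindromic: copy2 runs backwards
        flank_pairs = [(p1 - 1, p2 + length), (p1 + length, p2 - 1)]
    complemented = kind in ("complement", "palindromic")
    for x, y in flank_pairs:
        base_x = _CODE[int(draft.codes[x])]
        forbidden = comp[base_x] if complemented else base_x
        draft.codes[y] = _pick_other(rng, forbidden)


def _pick_other(rng: np.random.Generator, base: str) -> int:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}[base]
    choices = [i for i in range(4) if i != idx]
    return int(rng.choice(choices))


def _transform_copy(copy1: str, kind: str) -> str:
    if kind == "forward":
        return copy1
    if kind == "reverse":
        return copy1[::-1]
    if kind == "complement":
        return revcomp(copy1)[::-1]
    if kind == "palindromic":
        return revcomp(copy1)
    raise FixtureSpecError(f"unknown repeat kind {kind!r}")


def _mutate(rng: np.random.Generator, residues: str, count: int) -> str:
    if count == 0:
        return residues
    chars = list(residues)
    positions = rng.choice(len(chars), size=count, replace=False)
    for p in positions:
        chars[p] = _CODE[_pick_other(rng, chars[p])]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Fragmentation

@dataclass(frozen=True)
class FragmentationSpec:
    overlap_lengths: dict | None = None  # junction -> nt; default drawn U[19, 51]
    revcomp_ir_contig: bool = False
    drop_overlaps_at: tuple = ()
    gap_truncation: int = 1475
    seed: int = 0


def fragment_into_contigs(
    genome: NucleotideSequence,
    structure: QuadripartiteStructure,
    fspec: FragmentationSpec = FragmentationSpec(),
) -> tuple[Contig, Contig, Contig]:
    """Split the genome into LSC / IR / SSC draft contigs whose termini carry
    per-junction suffix-prefix overlaps (or planted gaps)."""
    rng = np.random.default_rng(fspec.seed)
    ov = dict(fspec.overlap_lengths or {})
    for junction in ("LSC-IRa", "IRa-SSC", "SSC-IRb", "IRb-LSC"):
        ov.setdefault(junction, int(rng.integers(19, 52)))
    g = genome.residues
    n = len(g)
    j1 = structure.ira[0].start
    j2 = structure.ira[0].end
    j3 = structure.irb[0].start

    lsc_start, lsc_end = 0, j1
    ssc_start, ssc_end = j2, j3
    t = fspec.gap_truncation
    lsc_left_ext = g[n - ov["IRb-LSC"] :]
    lsc_right_ext = g[j1 : j1 + ov["LSC-IRa"]]
    ssc_left_ext = g[j2 - ov["IRa-SSC"] : j2]
    ssc_right_ext = g[j3 : j3 + ov["SSC-IRb"]]
    if "IRb-LSC" in fspec.drop_overlaps_at:
        lsc_left_ext, lsc_start = "", t
    if "LSC-IRa" in fspec.drop_overlaps_at:
        lsc_right_ext, lsc_end = "", j1 - t
    if "IRa-SSC" in fspec.drop_overlaps_at:
        ssc_left_ext, ssc_start = "", j2 + t
    if "SSC-IRb" in fspec.drop_overlaps_at:
        ssc_right_ext, ssc_end = "", j3 - t

    lsc_res = lsc_left_ext + g[lsc_start:lsc_end] + lsc_right_ext
    ssc_res = ssc_left_ext + g[ssc_start:ssc_end] + ssc_right_ext
    ir_res = g[j1:j2]
    if fspec.revcomp_ir_contig:
        ir_res = revcomp(ir_res)
    return (
        Contig(NucleotideSequence("contig_lsc", lsc_res), "LSC"),
        Contig(NucleotideSequence("contig_ir", ir_res), "IR"),
        Contig(NucleotideSequence("contig_ssc", ssc_res), "SSC"),
    )


# ---------------------------------------------------------------------------
# Read simulation

@dataclass(frozen=True)
class ReadSimSpec:
    read_length: int = 79
    depth: float = 100.0
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 20:
            raise FixtureSpecError("read_length must be >= 20")
        if self.depth <= 0:
            raise FixtureSpecError("depth must be positive")


def simulate_reads(
    genome: NucleotideSequence, rspec: ReadSimSpec = ReadSimSpec()
) -> list[NucleotideSequence]:
    """Uniform circular-start reads on both strands with i.i.d. substitutions.

    Read count = round(depth * genome_length / read_length).
    """
    n = len(genome)
    if n < rspec.read_length:
        raise FixtureSpecError("genome shorter than read length")
    rng = np.random.default_rng(rspec.seed)
    count = int(round(rspec.depth * n / rspec.read_length))
    doubled = genome.residues + genome.residues[: rspec.read_length]
    starts = rng.integers(0, n, size=count)
    strands = rng.random(count) < 0.5
    reads = []
    for i in range(count):
        res = doubled[starts[i] : starts[i] + rspec.read_length]
        if rspec.substitution_rate > 0:
            hits = np.flatnonzero(rng.random(rspec.read_length) < rspec.substitution_rate)
            if hits.size:
                chars = list(res)
                for p in hits:
                    chars[p] = _CODE[_pick_other(rng, chars[p])]
                res = "".join(chars)
        if strands[i]:
            res = revcomp(res)
        reads.append(NucleotideSequence(id=f"read{i}", residues=res))
    return reads
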